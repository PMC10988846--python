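"""Methylation–expression integration for array-based DNA methylation.

Methylation arrays report a methylated (M) and unmethylated (U) intensity
per CpG probe.  With a constant offset ``a`` (default 100) these summarize
to

    β = M / (M + U + a)            (bounded methylation fraction, in [0, 1))
    M-value = log2((M + a)/(U + a))  (log-odds-like, unbounded)

A differentially methylated region (DMR) is a run of CpG probes; its
representative probe is the member with the largest probe-wise β range
across samples.  The representative probe's per-sample β values are
correlated (Spearman) with the matched, normalized expression of the DMR's
leading-edge gene, stratified by tissue (tumor / non_tumor) and patient
group.  Genomic coordinates are 1-based inclusive (array-annotation
convention).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .perturb import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_OFFSET",
    "ProbeIntensity",
    "DMRRecord",
    "CorrelationRecord",
    "m_value",
    "beta_value",
    "select_representative_probe",
    "spearman",
    "spearman_exact_p",
    "correlate_dmr_expression",
    "integrate_methylation_expression",
    "read_dmrs",
    "write_dmrs",
]

DEFAULT_OFFSET = 100.0

#: exact Spearman p by permutation enumeration up to this sample size
SPEARMAN_EXACT_N = 9


def m_value(methylated, unmethylated, a: float = DEFAULT_OFFSET):
    """M-value log2((M+a)/(U+a)); accepts scalars or arrays."""
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    if not a > 0:
        raise ValueError("offset a must be positive")
    out = np.log2((m + a) / (u + a))
    return float(out) if out.ndim == 0 else out


def beta_value(methylated, unmethylated, a: float = DEFAULT_OFFSET):
    """β-value M/(M+U+a) in [0, 1); accepts scalars or arrays."""
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    if not a > 0:
        raise ValueError("offset a must be positive")
    out = m / (m + u + a)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProbeIntensity:
    """Methylated/unmethylated intensities of one probe with offset ``a``."""

    probe: str
    M: float
    U: float
    a: float = DEFAULT_OFFSET

    def __post_init__(self):
        if self.M < 0 or self.U < 0:
            raise ValueError("intensities must be non-negative")
        if not self.a > 0:
            raise ValueError("offset a must be positive")

    @property
    def m_value(self) -> float:
        return m_value(self.M, self.U, self.a)

    @property
    def beta(self) -> float:
        return beta_value(self.M, self.U, self.a)


@dataclass(frozen=True)
class DMRRecord:
    """A differentially methylated region and its member probes.

    ``probes`` are listed in genomic (coordinate) order; ``maxdiff`` and
    ``meandiff`` are the region's maximum and mean CpG-wise methylation
    differences carried from upstream DMR calling, ``leading_gene`` the
    region's leading-edge gene.  Coordinates are 1-based inclusive.
    """

    region: str
    chrom: str
    start: int
    end: int
    probes: Tuple[str, ...]
    maxdiff: float
    meandiff: float
    leading_gene: str
    fisher_p: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "probes", tuple(self.probes))
        if not self.probes:
            raise ValueError(f"DMR {self.region} has no member probes")
        if self.start > self.end:
            raise ValueError(f"DMR {self.region}: start must be <= end")


@dataclass(frozen=True)
class CorrelationRecord:
    """Spearman correlation of methylation vs expression in one stratum."""

    gene: str
    dmr: str
    representative_probe: str
    tissue: str
    group: str
    rho: float
    p_value: float
    n: int

    def __post_init__(self):
        if not (-1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9) and not np.isnan(self.rho):
            raise ValueError("rho must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("correlations require at least 3 paired samples")


def select_representative_probe(dmr: DMRRecord, beta_matrix: pd.DataFrame) -> str:
    """Member probe with the largest β range across samples.

    Ties break to the probe earliest in genomic order (``dmr.probes`` order),
    which is deterministic across runs.
    """
    missing = [p for p in dmr.probes if p not in beta_matrix.index]
    if missing:
        raise KeyError(
            f"DMR {dmr.region}: probe(s) {missing} missing from the beta matrix"
        )
    sub = beta_matrix.loc[list(dmr.probes)]
    ranges = (sub.max(axis=1) - sub.min(axis=1)).to_numpy()
    return dmr.probes[int(np.argmax(ranges))]  # argmax takes the first maximum


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n p
# ---------------------------------------------------------------------------


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Spearman p by enumerating all rank permutations.

    Valid for tie-free data with n ≤ 9 (n! permutations are enumerated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > SPEARMAN_EXACT_N:
        raise ValueError(f"exact enumeration limited to n <= {SPEARMAN_EXACT_N}")
    if np.unique(x).size < n or np.unique(y).size < n:
        raise ValueError("exact enumeration requires tie-free data")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = n * (n**2 - 1)
    rho_obs = 1.0 - 6.0 * np.sum((rx - ry) ** 2) / denom
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    rhos = 1.0 - 6.0 * np.sum((perms - ry) ** 2, axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho and two-sided p.

    Exact permutation p for tie-free samples with n ≤ 9, otherwise the
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    tie_free = np.unique(x).size == x.size and np.unique(y).size == y.size
    if x.size <= SPEARMAN_EXACT_N and tie_free:
        return rho, spearman_exact_p(x, y)
    return rho, float(res.pvalue)


def correlate_dmr_expression(
    beta: pd.Series,
    expression: pd.Series,
    strata: pd.DataFrame,
    gene: str,
    dmr: str,
    representative_probe: str,
    min_n: int = 3,
) -> List[CorrelationRecord]:
    """Spearman correlations per (tissue, group) stratum and overall.

    ``beta`` and ``expression`` are per-sample series of the representative
    probe's β and the gene's normalized expression; ``strata`` maps samples
    to tissue and group columns.  Strata with fewer than ``min_n`` matched
    samples are skipped (logged).
    """
    samples = beta.index.intersection(expression.index).intersection(strata.index)
    if len(samples) == 0:
        raise ValueError("no overlapping samples between beta, expression and strata")
    records: List[CorrelationRecord] = []

    def _one(tissue: str, group: str, sel) -> None:
        ids = samples[sel]
        if len(ids) < min_n:
            logger.info(
                "stratum (%s, %s) for %s/%s has %d < %d samples; skipped",
                tissue, group, gene, dmr, len(ids), min_n,
            )
            return
        rho, p = spearman(beta.loc[ids].to_numpy(), expression.loc[ids].to_numpy())
        records.append(
            CorrelationRecord(gene, dmr, representative_probe, tissue, group, rho, p, len(ids))
        )

    tissues = strata.loc[samples, "tissue"]
    groups = strata.loc[samples, "group"]
    _one("all", "all", np.ones(len(samples), dtype=bool))
    for t in sorted(tissues.unique()):
        _one(t, "all", (tissues == t).to_numpy())
    for g in sorted(groups.unique()):
        _one("all", g, (groups == g).to_numpy())
    for t in sorted(tissues.unique()):
        for g in sorted(groups.unique()):
            _one(t, g, ((tissues == t) & (groups == g)).to_numpy())
    return records


def integrate_methylation_expression(
    dmrs: Iterable[DMRRecord],
    beta_matrix: pd.DataFrame,
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    min_n: int = 3,
    adjust: bool = True,
) -> pd.DataFrame:
    """Correlate every DMR's representative probe with its leading gene.

    ``metadata`` must have columns sample, group, tissue.  Returns one row
    per (gene, DMR, tissue, group) stratum with raw p and, by default, a BH
    adjusted p across all reported records.
    """
    required = {"sample", "group", "tissue"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    strata = metadata.set_index("sample")[["tissue", "group"]]
    all_records: List[CorrelationRecord] = []
    for dmr in dmrs:
        gene = dmr.leading_gene
        if gene not in expression.index:
            logger.info("DMR %s: leading gene %s absent from expression; skipped", dmr.region, gene)
            continue
        probe = select_representative_probe(dmr, beta_matrix)
        all_records.extend(
            correlate_dmr_expression(
                beta_matrix.loc[probe],
                expression.loc[gene],
                strata,
                gene=gene,
                dmr=dmr.region,
                representative_probe=probe,
                min_n=min_n,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in all_records])
    if adjust and len(out):
        out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# DMR table I/O (TSV; probes as a ';'-separated, coordinate-ordered list)
# ---------------------------------------------------------------------------

_DMR_COLUMNS = [
    "region", "chrom", "start", "end", "probes", "maxdiff", "meandiff",
    "leading_gene", "fisher_p",
]


def read_dmrs(path) -> List[DMRRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_DMR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DMR table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DMRRecord(
                region=str(row["region"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                probes=tuple(str(row["probes"]).split(";")),
                maxdiff=float(row["maxdiff"]),
                meandiff=float(row["meandiff"]),
                leading_gene=str(row["leading_gene"]),
                fisher_p=float(row["fisher_p"]) if pd.notna(row["fisher_p"]) else None,
            )
        )
    return records


def write_dmrs(dmrs: Iterable[DMRRecord], path) -> None:
    rows = []
    for d in dmrs:
        rows.append(
            {
                "region": d.region,
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "probes": ";".join(d.probes),
                "maxdiff": d.maxdiff,
                "meandiff": d.meandiff,
                "leading_gene": d.leading_gene,
                "fisher_p": d.fisher_p,
            }
        )
    pd.DataFrame(rows, columns=_DMR_COLUMNS).to_csv(path, sep="\t", index=False)
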
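"""Omics-driven personalization of Boolean network models.

Per-patient omics become subject-specific model parameters:

* discrete evidence (mutations with a functional-effect label, extreme copy
  number) forces node activities to a constant 0/1 — an inactivating
  mutation or a deep deletion (ploidy −2) forces 0, an activating mutation
  or a high amplification (ploidy +2) forces 1;
* continuous evidence (cohort-normalized expression x ∈ [0,1]) sets the
  transition rates, up = scale·x and down = scale·(1−x), and the initial
  probability of being ON, initial_p_on = x.  Higher expression therefore
  means a higher propensity to be ON; for an input-free node the implied
  two-state chain has stationary P(ON) = x.

Copy-number log-ratios (lRR, as printed by allele-specific segmentation)
are discretized to ploidy categories −2…+2 with the half-open intervals
−2: lRR ≤ −1.1; −1: −1.1 < lRR ≤ −0.2; 0: −0.2 < lRR ≤ 0.2;
1: 0.2 < lRR ≤ 0.7; 2: lRR > 0.7.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .logic import BooleanNetwork
from .simulate import TransitionRates

logger = logging.getLogger(__name__)

__all__ = [
    "EFFECTS",
    "MutationCall",
    "PatientProfile",
    "PersonalizedModel",
    "ForcingPolicy",
    "discretize_lrr",
    "discretize_lrr_frame",
    "normalize_expression",
    "apply_discrete_forcings",
    "derive_rates_and_initial",
    "build_personalized_model",
    "read_mutations",
    "read_cnv",
    "read_expression",
    "read_metadata",
    "read_alias_table",
    "cohort_profiles",
]

EFFECTS = frozenset({"activating", "inactivating", "unknown"})
PLOIDY_LEVELS = frozenset({-2, -1, 0, 1, 2})

#: lRR upper bounds (inclusive) of the ploidy categories −2, −1, 0, 1; above
#: the last bound the category is 2.
LRR_BOUNDS = (-1.1, -0.2, 0.2, 0.7)


@dataclass(frozen=True)
class MutationCall:
    """A somatic mutation in one sample, annotated with its functional effect."""

    gene: str
    effect: str
    sample: str

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise ValueError(
                f"mutation effect must be one of {sorted(EFFECTS)}, got {self.effect!r}"
            )


@dataclass(frozen=True)
class PatientProfile:
    """One patient's omics: mutations, gene ploidy, and normalized expression."""

    sample: str
    group: str
    mutations: Tuple[MutationCall, ...] = ()
    ploidy: Mapping[str, int] = field(default_factory=dict)
    expression: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.group:
            raise ValueError("group label must be non-empty")
        object.__setattr__(self, "mutations", tuple(self.mutations))
        object.__setattr__(self, "ploidy", dict(self.ploidy))
        object.__setattr__(self, "expression", dict(self.expression))
        for gene, p in self.ploidy.items():
            if int(p) not in PLOIDY_LEVELS:
                raise ValueError(f"ploidy for {gene!r} must be in {{-2..2}}, got {p}")
        for gene, x in self.expression.items():
            if not (0.0 <= x <= 1.0):
                raise ValueError(
                    f"normalized expression for {gene!r} must lie in [0,1], got {x}"
                )


@dataclass(frozen=True)
class PersonalizedModel:
    """A network plus per-patient forcings, rates, and initial ON-probabilities."""

    network: BooleanNetwork
    forcings: Mapping[str, int]
    rates: TransitionRates
    initial_p_on: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "forcings", dict(self.forcings))
        object.__setattr__(self, "initial_p_on", dict(self.initial_p_on))
        nodes = set(self.network.nodes)
        for node, v in self.forcings.items():
            if node not in nodes:
                raise ValueError(f"forced node {node!r} is not in the network")
            if v not in (0, 1):
                raise ValueError(f"forcing for {node!r} must be 0 or 1, got {v}")
        forced = set(self.forcings)
        if set(self.rates.up) != nodes - forced:
            raise ValueError("rates must cover exactly the non-forced nodes")
        if set(self.initial_p_on) != nodes:
            raise ValueError("initial_p_on must cover every node")
        for node, p in self.initial_p_on.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"initial_p_on for {node!r} must lie in [0,1]")
        for node, v in self.forcings.items():
            if self.initial_p_on[node] != float(v):
                raise ValueError(
                    f"initial_p_on for forced node {node!r} must equal its forced value"
                )


@dataclass(frozen=True)
class ForcingPolicy:
    """How discrete evidence maps to forcings and how conflicts resolve.

    ``precedence`` names the evidence that wins a mutation-vs-CNV conflict;
    with ``strict`` any conflict is an error instead.  ``non_forcible``
    protects nodes without a single genomic locus (fusion nodes such as
    AR_ERG) from ever being forced by omics.
    """

    precedence: str = "mutation"
    strict: bool = False
    non_forcible: FrozenSet[str] = frozenset({"AR_ERG"})

    def __post_init__(self):
        if self.precedence not in ("mutation", "cnv"):
            raise ValueError("precedence must be 'mutation' or 'cnv'")


# ---------------------------------------------------------------------------
# Discretization & normalization
# ---------------------------------------------------------------------------


def discretize_lrr(lrr: float) -> int:
    """Ploidy category in {−2,−1,0,1,2} for a copy-number log-ratio.

    Interval upper bounds are inclusive; the top class is open (lRR > 0.7 → 2).
    """
    lrr = float(lrr)
    if not math.isfinite(lrr):
        raise ValueError(f"lRR must be finite, got {lrr}")
    return int(np.digitize(lrr, LRR_BOUNDS, right=True)) - 2


def discretize_lrr_frame(lrr: pd.DataFrame) -> pd.DataFrame:
    """Vectorized lRR→ploidy over a gene × sample matrix."""
    values = lrr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("lRR matrix contains non-finite values")
    out = np.digitize(values, LRR_BOUNDS, right=True) - 2
    return pd.DataFrame(out, index=lrr.index, columns=lrr.columns)


def normalize_expression(raw: pd.DataFrame, method: str = "minmax") -> pd.DataFrame:
    """Scale a gene × sample matrix to [0,1] per gene across the cohort.

    ``minmax`` maps the cohort minimum to 0 and maximum to 1; constant genes
    map to 0.5.  ``rank`` uses rank percentiles (mid-ranks for ties), which
    is invariant to any strictly monotone transform of a gene's values.
    """
    if raw.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples as a cohort reference")
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    if method == "minmax":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (values - lo) / span
        out[np.broadcast_to(span == 0, out.shape)] = 0.5
    elif method == "rank":
        m = values.shape[1]
        ranks = np.apply_along_axis(rankdata, 1, values)
        out = (ranks - 1.0) / (m - 1.0)
        const = values.max(axis=1) == values.min(axis=1)
        out[const, :] = 0.5
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


# ---------------------------------------------------------------------------
# Forcings, rates, model assembly
# ---------------------------------------------------------------------------


def _map_gene(gene: str, aliases: Optional[Mapping[str, str]]) -> str:
    if aliases and gene in aliases:
        return aliases[gene]
    return gene


def apply_discrete_forcings(
    profile: PatientProfile,
    network: BooleanNetwork,
    policy: Optional[ForcingPolicy] = None,
    aliases: Optional[Mapping[str, str]] = None,
) -> Dict[str, int]:
    """Forced node values from mutations and extreme copy number.

    Inactivating mutation or ploidy −2 force 0; activating mutation or
    ploidy +2 force 1; unknown effects and |ploidy| ≤ 1 contribute nothing.
    Genes absent from the network are ignored (logged).  Conflicts resolve
    by ``policy.precedence`` (logged) unless ``policy.strict``.
    """
    policy = policy or ForcingPolicy()
    nodes = set(network.nodes)

    mut_evidence: Dict[str, set] = {}
    for call in profile.mutations:
        node = _map_gene(call.gene, aliases)
        if node not in nodes:
            logger.info("sample %s: mutated gene %s not in network; ignored", profile.sample, call.gene)
            continue
        if node in policy.non_forcible:
            logger.info("sample %s: node %s is non-forcible; mutation ignored", profile.sample, node)
            continue
        if call.effect != "unknown":
            mut_evidence.setdefault(node, set()).add(call.effect)

    mut_forcing: Dict[str, int] = {}
    for node, effects in mut_evidence.items():
        if len(effects) > 1:
            msg = f"sample {profile.sample}: conflicting mutation effects for {node}: {sorted(effects)}"
            if policy.strict:
                raise ValueError(msg)
            logger.warning("%s; treated as unknown", msg)
            continue
        mut_forcing[node] = 1 if effects == {"activating"} else 0

    cnv_forcing: Dict[str, int] = {}
    for gene, p in profile.ploidy.items():
        node = _map_gene(gene, aliases)
        if node not in nodes:
            logger.info("sample %s: CNV gene %s not in network; ignored", profile.sample, gene)
            continue
        if node in policy.non_forcible:
            continue
        if p == -2:
            cnv_forcing[node] = 0
        elif p == 2:
            cnv_forcing[node] = 1

    forcings = dict(cnv_forcing)
    for node, v in mut_forcing.items():
        if node in cnv_forcing and cnv_forcing[node] != v:
            msg = (
                f"sample {profile.sample}: node {node} has conflicting evidence "
                f"(mutation → {v}, CNV → {cnv_forcing[node]})"
            )
            if policy.strict:
                raise ValueError(msg)
            winner = v if policy.precedence == "mutation" else cnv_forcing[node]
            logger.warning("%s; %s evidence wins → %d", msg, policy.precedence, winner)
            forcings[node] = winner
        else:
            forcings[node] = v
    return forcings


def derive_rates_and_initial(
    profile: PatientProfile,
    network: BooleanNetwork,
    scale: float = 1.0,
    eps: float = 0.01,
    aliases: Optional[Mapping[str, str]] = None,
) -> Tuple[TransitionRates, Dict[str, float]]:
    """Transition rates and initial ON-probabilities from normalized expression.

    For node i with expression x (clamped to [eps, 1−eps]): up = scale·x,
    down = scale·(1−x), initial_p_on = x.  Nodes without expression data get
    symmetric defaults up = down = scale/2 and initial_p_on = 0.5 (logged).
    """
    if not (scale > 0):
        raise ValueError("scale must be strictly positive")
    expr: Dict[str, float] = {}
    for gene, x in profile.expression.items():
        expr[_map_gene(gene, aliases)] = x
    up: Dict[str, float] = {}
    down: Dict[str, float] = {}
    init: Dict[str, float] = {}
    for node in network.nodes:
        if node in expr:
            x = min(max(expr[node], eps), 1.0 - eps)
            up[node] = scale * x
            down[node] = scale * (1.0 - x)
            init[node] = x
        else:
            logger.info("sample %s: no expression for node %s; symmetric defaults", profile.sample, node)
            up[node] = down[node] = scale / 2.0
            init[node] = 0.5
    return TransitionRates(up, down), init


def build_personalized_model(
    profile: PatientProfile,
    network: BooleanNetwork,
    policy: Optional[ForcingPolicy] = None,
    scale: float = 1.0,
    aliases: Optional[Mapping[str, str]] = None,
) -> PersonalizedModel:
    """Compose forcings, rates and initial probabilities into a subject model.

    Forcings override expression-derived rates and initial probabilities.
    """
    forcings = apply_discrete_forcings(profile, network, policy, aliases)
    rates, init = derive_rates_and_initial(profile, network, scale=scale, aliases=aliases)
    up = {n: r for n, r in rates.up.items() if n not in forcings}
    down = {n: r for n, r in rates.down.items() if n not in forcings}
    for node, v in forcings.items():
        init[node] = float(v)
    free_rates = TransitionRates(up, down) if up else TransitionRates({}, {})
    return PersonalizedModel(network, forcings, free_rates, init)


# ---------------------------------------------------------------------------
# Cohort table I/O (TSV schemas)
# ---------------------------------------------------------------------------


def read_mutations(path) -> pd.DataFrame:
    """Mutation TSV with columns sample, gene, effect."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "gene", "effect"}
    if not required.issubset(df.columns):
        raise ValueError(f"mutation table must have columns {sorted(required)}")
    bad = set(df["effect"]) - EFFECTS
    if bad:
        raise ValueError(f"unknown mutation effects {sorted(bad)}")
    return df


def read_cnv(path) -> pd.DataFrame:
    """Copy-number gene × sample matrix (lRR floats or ploidy integers)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(path) -> pd.DataFrame:
    """Expression gene × sample matrix (raw, non-negative)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample, group (optionally tissue)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError("metadata table must have columns sample, group")
    return df


def read_alias_table(path) -> Dict[str, str]:
    """Alias TSV mapping omics gene symbols to network node names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"omics_gene", "network_node"}.issubset(df.columns):
        raise ValueError("alias table must have columns omics_gene, network_node")
    return dict(zip(df["omics_gene"], df["network_node"]))


def cohort_profiles(
    metadata: pd.DataFrame,
    mutations: Optional[pd.DataFrame] = None,
    cnv: Optional[pd.DataFrame] = None,
    expression: Optional[pd.DataFrame] = None,
    cnv_kind: str = "lrr",
    normalization: str = "minmax",
) -> Dict[str, PatientProfile]:
    """Assemble per-sample profiles from cohort tables.

    Expression is normalized across the cohort once; all other channels are
    per-sample, so one sample's profile does not depend on other samples'
    mutations or CNVs.
    """
    if cnv_kind not in ("lrr", "ploidy"):
        raise ValueError("cnv_kind must be 'lrr' or 'ploidy'")
    ploidy_df = None
    if cnv is not None:
        ploidy_df = discretize_lrr_frame(cnv) if cnv_kind == "lrr" else cnv.astype(int)
    norm_df = normalize_expression(expression, normalization) if expression is not None else None

    profiles: Dict[str, PatientProfile] = {}
    for _, row in metadata.iterrows():
        sample, group = str(row["sample"]), str(row["group"])
        calls: Tuple[MutationCall, ...] = ()
        if mutations is not None:
            sub = mutations[mutations["sample"] == sample]
            calls = tuple(
                MutationCall(gene=g, effect=e, sample=sample)
                for g, e in zip(sub["gene"], sub["effect"])
            )
        ploidy = {}
        if ploidy_df is not None and sample in ploidy_df.columns:
            ploidy = ploidy_df[sample].to_dict()
        expr = {}
        if norm_df is not None and sample in norm_df.columns:
            expr = norm_df[sample].to_dict()
        profiles[sample] = PatientProfile(sample, group, calls, ploidy, expr)
    return profiles
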
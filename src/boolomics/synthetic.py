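"""Synthetic fixtures: toy and random Boolean networks, two-group omics
cohorts with planted effects, and coupled methylation–expression data.

The generators emulate the *structure* of a two-group (AA/EA) prostate
cancer study — a mutation list with functional-effect labels, a copy-number
log-ratio matrix, an expression matrix, sample metadata, and probe-level
methylation β values organized into DMRs — not the marginal distributions
of any real dataset.  Every generator is deterministic given its seed.

The toy AR network is hand-curated and frozen so that exact
master-equation expectations (e.g. the direction of each node's response
to an AR knockout) are fixed test oracles: AR drives AR_ERG and ZBTB17 and
represses the branches feeding SMAD and IDH1, so knocking AR out lowers
AR_ERG/ZBTB17 activity and raises SMAD/IDH1 activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .logic import (
    BooleanNetwork,
    parse_rules,
    semantic_regulators,
    write_pathway_map,
    write_rules,
)
from .methylation import DMRRecord, write_dmrs
from .personalize import EFFECTS, PatientProfile, cohort_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "TOY_RULES",
    "TOY_PATHWAYS",
    "toy_ar_network",
    "generate_random_network",
    "PlantedEffect",
    "CohortSpec",
    "CohortTables",
    "simulate_cohort",
    "MethylationTables",
    "simulate_methylation_coupling",
    "write_cohort",
    "recovery_cohort_spec",
]

# ---------------------------------------------------------------------------
# Toy AR signalling fixture (frozen)
# ---------------------------------------------------------------------------

#: Hand-curated 11-node AR signalling fixture.  Androgen is a constant-ON
#: ligand input (therapy-naïve disease with sustained androgen
#: availability); GrowthFactor and TGFB are self-sustaining input tones
#: that hold their patient-specific initial value.  AR transduces
#: androgen; the AR_ERG fusion and ZBTB17 lie downstream of AR; AR
#: represses the branches feeding SMAD (which integrates TGF-β ligand
#: tone with AR-derepression) and IDH1.  The cell cycle arm (CyclinD →
#: E2F → Proliferation) integrates AR_ERG, growth signalling and ZBTB17
#: (a Myc-interacting cell-cycle brake).
TOY_RULES = """\
targets, factors
Androgen, 1
GrowthFactor, GrowthFactor
AR, Androgen
AR_ERG, AR
ZBTB17, AR | AR_ERG
TGFB, TGFB
SMAD, TGFB | !AR
IDH1, !AR
CyclinD, AR_ERG | GrowthFactor
E2F, CyclinD & !ZBTB17
Proliferation, E2F
"""

TOY_PATHWAYS: Dict[str, str] = {
    "Androgen": "Input",
    "GrowthFactor": "Input",
    "AR": "AR",
    "AR_ERG": "AR",
    "ZBTB17": "AR",
    "TGFB": "TGF_beta",
    "SMAD": "TGF_beta",
    "IDH1": "Metabolic",
    "CyclinD": "Cell_cycle",
    "E2F": "Cell_cycle",
    "Proliferation": "Cell_cycle",
}


#: Toy-fixture nodes that are not single transcripts — ligand tones
#: (Androgen, GrowthFactor), a protein-family activity (SMAD) and a
#: phenotype read-out (Proliferation) — and therefore have no row in the
#: omics matrices the cohort generator emulates.
TOY_NON_GENE_NODES = ("Androgen", "GrowthFactor", "SMAD", "Proliferation")


def toy_ar_network() -> BooleanNetwork:
    """The frozen toy AR signalling network with its pathway map."""
    return parse_rules(TOY_RULES, pathway_groups=TOY_PATHWAYS)


# ---------------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------------


def _table_to_expression(order: Sequence[str], table: np.ndarray) -> str:
    """Disjunctive normal form over ``order`` for a truth table."""
    minterms = []
    for i, v in enumerate(table):
        if not v:
            continue
        lits = []
        for j, name in enumerate(order):
            lits.append(name if (i >> j) & 1 else f"!{name}")
        minterms.append(" & ".join(lits) if len(lits) > 1 else lits[0])
    return " | ".join(f"({m})" if " & " in m and len(minterms) > 1 else m for m in minterms)


def generate_random_network(
    n_nodes: int, max_regulators: int, seed: int
) -> BooleanNetwork:
    """Random network: 1..max_regulators regulators and a non-vacuous rule each.

    Every listed regulator is semantically essential (some flip of it
    changes the rule's output) and no rule is constant.  Reproducible from
    ``seed``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be at least 1")
    if not (1 <= max_regulators <= n_nodes):
        raise ValueError("max_regulators must lie in [1, n_nodes]")
    rng = np.random.default_rng([int(seed), 7])
    names = [f"N{i+1}" for i in range(n_nodes)]
    lines = ["targets, factors"]
    for i, name in enumerate(names):
        k = int(rng.integers(1, max_regulators + 1))
        regs = sorted(rng.choice(n_nodes, size=k, replace=False))
        order = [names[j] for j in regs]
        for _ in range(1000):
            table = rng.integers(0, 2, size=2**k).astype(np.uint8)
            if table.min() == table.max():
                continue  # constant
            idx = np.arange(table.size)
            if all(np.any(table[idx] != table[idx ^ (1 << j)]) for j in range(k)):
                break
        else:  # pragma: no cover - k <= ~6 always admits such a table quickly
            raise RuntimeError("failed to draw a non-vacuous truth table")
        lines.append(f"{name}, {_table_to_expression(order, table)}")
    network = parse_rules("\n".join(lines) + "\n")
    # construction guarantee: syntactic regulators == semantic dependencies
    for rule in network.rules:
        assert semantic_regulators(rule) == set(rule.regulators)
    return network


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

CHANNELS = ("mutation_rate", "cnv", "expression_shift", "methylation_coupling")


@dataclass(frozen=True)
class PlantedEffect:
    """A group-specific difference planted into one generator channel.

    magnitude semantics by channel: mutation_rate — per-sample mutation
    probability of ``target`` in ``group``; cnv — mean shift of the lRR of
    ``target`` in ``group`` (log-ratio units); expression_shift — additive
    shift of log2 expression of ``target`` in ``group``; methylation_coupling
    — target absolute Spearman correlation (in [0, 1]) between the
    representative probe's β and expression of ``target``, with inverse
    (negative) coupling.
    """

    target: str
    channel: str
    magnitude: float
    group: Optional[str] = None  # default: first group label
    effect: str = "inactivating"  # functional label for mutation_rate channel

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.channel == "mutation_rate" and not (0 <= self.magnitude <= 1):
            raise ValueError("mutation_rate magnitude is a probability")
        if self.channel == "methylation_coupling" and not (0 <= self.magnitude <= 1):
            raise ValueError("methylation_coupling magnitude is |rho|, in [0, 1]")
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {sorted(EFFECTS)}")


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped synthetic cohort: two groups with three omics channels.

    Defaults mirror the modelled study conditions: two patient groups
    (AA/EA), tumour tissue, background mutation probability 0.05 per gene,
    lRR noise SD 0.3 (so |ploidy| = 2 arises essentially only under planted
    shifts), and log-normal expression with per-gene baselines.
    """

    network: BooleanNetwork
    n_per_group: int = 10
    group_labels: Tuple[str, str] = ("AA", "EA")
    planted_effects: Tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.5
    seed: int = 0
    mutation_rate: float = 0.01
    lrr_sd: float = 0.3
    log2_baseline_range: Tuple[float, float] = (3.0, 8.0)
    non_gene_nodes: Tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "non_gene_nodes", tuple(self.non_gene_nodes))
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be at least 3")
        if len(self.group_labels) != 2 or len(set(self.group_labels)) != 2:
            raise ValueError("group_labels must be two distinct labels")
        genes = set(self.genes)
        for eff in self.planted_effects:
            if eff.group is not None and eff.group not in self.group_labels:
                raise ValueError(f"planted effect group {eff.group!r} not in group_labels")
            if eff.channel != "methylation_coupling" and eff.target not in genes:
                raise ValueError(
                    f"planted {eff.channel} target {eff.target!r} absent from the gene universe"
                )

    @property
    def genes(self) -> Tuple[str, ...]:
        """Omics gene universe: network nodes that are single transcripts."""
        return tuple(n for n in self.network.nodes if n not in self.non_gene_nodes)

    def effects_for(self, channel: str) -> Dict[str, PlantedEffect]:
        return {e.target: e for e in self.planted_effects if e.channel == channel}

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        """Load a spec from YAML (rules inline under ``rules`` or via ``rules_file``)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "rules" in data:
            network = parse_rules(data.pop("rules"))
        elif "rules_file" in data:
            rules_path = Path(data.pop("rules_file"))
            if not rules_path.is_absolute():
                rules_path = Path(path).parent / rules_path
            network = parse_rules(rules_path.read_text())
        else:
            network = toy_ar_network()
        effects = tuple(
            PlantedEffect(**e) for e in data.pop("planted_effects", [])
        )
        for key in ("group_labels", "log2_baseline_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(network=network, planted_effects=effects, **data)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTables:
    """Generated cohort in the exact TSV schemas the personalization consumes."""

    mutations: pd.DataFrame  # columns sample, gene, effect
    cnv_lrr: pd.DataFrame  # gene × sample log-ratios
    expression: pd.DataFrame  # gene × sample raw expression
    metadata: pd.DataFrame  # columns sample, group, tissue

    def profiles(self) -> Dict[str, PatientProfile]:
        return cohort_profiles(
            self.metadata,
            mutations=self.mutations,
            cnv=self.cnv_lrr,
            expression=self.expression,
            cnv_kind="lrr",
        )


def simulate_cohort(spec: CohortSpec) -> Tuple[Dict[str, PatientProfile], CohortTables]:
    """Draw a two-group cohort (mutations, CNV log-ratios, expression).

    Mutations are per-gene Bernoulli (group-specific probability where
    planted); lRR is Normal(shift, lrr_sd) with a planted group shift; log2
    expression is a per-gene baseline plus Normal(0, noise_sd) noise plus a
    planted group shift.  With no planted effects the two groups are
    exchangeable.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng([int(spec.seed), 11])
    genes = list(spec.genes)
    samples, groups = [], []
    for label in spec.group_labels:
        for i in range(spec.n_per_group):
            samples.append(f"{label}_{i+1:02d}")
            groups.append(label)
    metadata = pd.DataFrame({"sample": samples, "group": groups, "tissue": "tumor"})

    mut_effects = spec.effects_for("mutation_rate")
    cnv_effects = spec.effects_for("cnv")
    expr_effects = spec.effects_for("expression_shift")

    lo, hi = spec.log2_baseline_range
    baseline = rng.uniform(lo, hi, size=len(genes))

    mut_rows: List[dict] = []
    lrr = np.empty((len(genes), len(samples)))
    log2_expr = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        for si, (sample, group) in enumerate(zip(samples, groups)):
            rate = spec.mutation_rate
            effect_label = None
            planted = mut_effects.get(gene)
            if planted is not None and group == (planted.group or spec.group_labels[0]):
                rate = planted.magnitude
                effect_label = planted.effect
            if rng.random() < rate:
                if effect_label is None:
                    effect_label = str(
                        rng.choice(["inactivating", "activating", "unknown"])
                    )
                mut_rows.append({"sample": sample, "gene": gene, "effect": effect_label})

            shift = 0.0
            planted = cnv_effects.get(gene)
            if planted is not None and group == (planted.group or spec.group_labels[0]):
                shift = planted.magnitude
            lrr[gi, si] = shift + rng.normal(0.0, spec.lrr_sd)

            shift = 0.0
            planted = expr_effects.get(gene)
            if planted is not None and group == (planted.group or spec.group_labels[0]):
                shift = planted.magnitude
            log2_expr[gi, si] = baseline[gi] + shift + rng.normal(0.0, spec.noise_sd)

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "effect"])
    cnv_lrr = pd.DataFrame(np.round(lrr, 6), index=pd.Index(genes, name="gene"), columns=samples)
    expression = pd.DataFrame(
        np.round(np.exp2(log2_expr), 6), index=pd.Index(genes, name="gene"), columns=samples
    )
    tables = CohortTables(mutations, cnv_lrr, expression, metadata)
    return tables.profiles(), tables


def toy_cohort_spec(
    seed: int,
    n_per_group: int = 10,
    planted_effects: Tuple[PlantedEffect, ...] = (),
) -> CohortSpec:
    """Cohort spec on the toy AR fixture with its non-transcript nodes excluded."""
    return CohortSpec(
        network=toy_ar_network(),
        n_per_group=n_per_group,
        planted_effects=planted_effects,
        seed=seed,
        non_gene_nodes=TOY_NON_GENE_NODES,
    )


def recovery_cohort_spec(seed: int, n_per_group: int = 10) -> CohortSpec:
    """Default recovery experiment: expression of TGFB (the SMAD regulator in
    the toy fixture) shifted up by 4 log2 units in the AA group, read out as
    the between-group difference in ΔAUC(SMAD) after AR knockout."""
    return toy_cohort_spec(
        seed,
        n_per_group=n_per_group,
        planted_effects=(PlantedEffect("TGFB", "expression_shift", 4.0, group="AA"),),
    )


# ---------------------------------------------------------------------------
# Coupled methylation–expression generation
# ---------------------------------------------------------------------------

N_FILLER_GENES = 8
TISSUES = ("tumor", "non_tumor")


@dataclass(frozen=True)
class MethylationTables:
    """Probe-level β values, DMR table, matched expression and strata metadata."""

    beta: pd.DataFrame  # probe × sample β values
    dmrs: Tuple[DMRRecord, ...]
    expression: pd.DataFrame  # gene × sample normalized-like expression
    metadata: pd.DataFrame  # columns sample, group, tissue


def _coupled_normals(rng, n: int, target_abs_rho: float) -> Tuple[np.ndarray, np.ndarray]:
    """(z1, z2) standard normals with population Spearman(z1, z2) = −target.

    Uses the Gaussian-copula identity rho_S = (6/π)·asin(r/2): Spearman is
    rank-based, so any monotone transforms of z1/z2 keep the target.
    """
    z1 = rng.normal(size=n)
    if target_abs_rho >= 1.0:
        return z1, -z1
    if target_abs_rho <= 0.0:
        return z1, rng.normal(size=n)
    r = 2.0 * np.sin(np.pi * (-target_abs_rho) / 6.0)
    z2 = r * z1 + np.sqrt(1.0 - r**2) * rng.normal(size=n)
    return z1, z2


def simulate_methylation_coupling(spec: CohortSpec) -> MethylationTables:
    """β matrix, DMR table and expression with planted inverse coupling.

    For every ``methylation_coupling`` planted effect the target gene's DMR
    gets a representative probe whose β is a monotone-decreasing noisy
    function of expression, with the planted |Spearman rho| per (tissue,
    group) stratum; filler genes are uncoupled.  The representative probe
    has the largest β range in its DMR by construction.
    """
    targets = spec.effects_for("methylation_coupling")
    if not targets:
        raise ValueError("spec has no methylation_coupling planted effect")
    rng = np.random.default_rng([int(spec.seed), 13])

    samples, groups, tissues = [], [], []
    for tissue in TISSUES:
        for label in spec.group_labels:
            for i in range(spec.n_per_group):
                samples.append(f"{label}_{tissue}_{i+1:02d}")
                groups.append(label)
                tissues.append(tissue)
    metadata = pd.DataFrame({"sample": samples, "group": groups, "tissue": tissues})
    n_samples = len(samples)

    genes = list(targets) + [f"GENE{i+1:02d}" for i in range(N_FILLER_GENES)]
    probe_rows: List[np.ndarray] = []
    probe_ids: List[str] = []
    dmrs: List[DMRRecord] = []
    expr = np.empty((len(genes), n_samples))
    position = 10_000
    probe_counter = 0

    strata_slices = []
    start = 0
    for tissue in TISSUES:
        for label in spec.group_labels:
            strata_slices.append(slice(start, start + spec.n_per_group))
            start += spec.n_per_group

    for gi, gene in enumerate(genes):
        target_rho = targets[gene].magnitude if gene in targets else None
        z1 = np.empty(n_samples)
        z2 = np.empty(n_samples)
        for sl in strata_slices:
            n = sl.stop - sl.start
            if target_rho is None:
                z1[sl], z2[sl] = rng.normal(size=n), rng.normal(size=n)
            else:
                z1[sl], z2[sl] = _coupled_normals(rng, n, target_rho)
        mu = rng.uniform(*spec.log2_baseline_range)
        expr[gi] = np.exp2(mu + z1)

        n_probes = int(rng.integers(3, 11))
        rep_index = int(rng.integers(0, n_probes))
        positions = position + np.cumsum(rng.integers(50, 400, size=n_probes))
        position = int(positions[-1]) + 2_000
        member_ids = []
        member_betas = []
        base = rng.uniform(0.3, 0.7)
        for j in range(n_probes):
            probe_counter += 1
            pid = f"cg{probe_counter:06d}"
            member_ids.append(pid)
            if j == rep_index:
                beta = 1.0 / (1.0 + np.exp(-1.5 * z2))
            else:
                beta = np.clip(base + rng.normal(0.0, 0.02, size=n_samples), 0.01, 0.99)
            member_betas.append(beta)
            probe_ids.append(pid)
            probe_rows.append(beta)
        betas = np.array(member_betas)
        tumor_mask = metadata["tissue"].to_numpy() == "tumor"
        diffs = betas[:, tumor_mask].mean(axis=1) - betas[:, ~tumor_mask].mean(axis=1)
        dmrs.append(
            DMRRecord(
                region=f"DMR_{gene}",
                chrom="chr1",
                start=int(positions[0]),
                end=int(positions[-1]),
                probes=tuple(member_ids),
                maxdiff=float(diffs[np.argmax(np.abs(diffs))]),
                meandiff=float(diffs.mean()),
                leading_gene=gene,
                fisher_p=0.01,
            )
        )

    beta_df = pd.DataFrame(
        np.round(np.array(probe_rows), 6), index=pd.Index(probe_ids, name="probe"), columns=samples
    )
    expr_df = pd.DataFrame(
        np.round(expr, 6), index=pd.Index(genes, name="gene"), columns=samples
    )
    return MethylationTables(beta_df, tuple(dmrs), expr_df, metadata)


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------


def write_cohort(
    spec: CohortSpec, outdir, include_methylation: bool = False
) -> Dict[str, Path]:
    """Write a generated cohort to TSV/bnet files; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, tables = simulate_cohort(spec)
    paths: Dict[str, Path] = {}

    paths["rules"] = outdir / "rules.bnet"
    paths["rules"].write_text(write_rules(spec.network))
    if spec.network.pathway_groups:
        paths["pathway_map"] = outdir / "pathway_map.tsv"
        write_pathway_map(spec.network.pathway_groups, paths["pathway_map"])
    paths["mutations"] = outdir / "mutations.tsv"
    tables.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    paths["cnv_lrr"] = outdir / "cnv_lrr.tsv"
    tables.cnv_lrr.to_csv(paths["cnv_lrr"], sep="\t")
    paths["expression"] = outdir / "expression.tsv"
    tables.expression.to_csv(paths["expression"], sep="\t")
    paths["metadata"] = outdir / "metadata.tsv"
    tables.metadata.to_csv(paths["metadata"], sep="\t", index=False)

    if include_methylation:
        meth = simulate_methylation_coupling(spec)
        paths["beta"] = outdir / "beta.tsv"
        meth.beta.to_csv(paths["beta"], sep="\t")
        paths["dmrs"] = outdir / "dmrs.tsv"
        write_dmrs(meth.dmrs, paths["dmrs"])
        paths["meth_expression"] = outdir / "meth_expression.tsv"
        meth.expression.to_csv(paths["meth_expression"], sep="\t")
        paths["meth_metadata"] = outdir / "meth_metadata.tsv"
        meth.metadata.to_csv(paths["meth_metadata"], sep="\t", index=False)
    return paths
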
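"""In-silico knockout experiments and between-group ΔAUC statistics.

A perturbation forces chosen nodes to fixed values on top of a personalized
model — e.g. fixing the androgen-receptor node AR to 0 mimics prolonged
pharmacological AR inhibition.  Each subject model is simulated before and
after the perturbation, per-node activity is integrated into AUCs, and the
node statistic is the relative change

    ΔAUC(%) = (AUC_ap − AUC_bp) / AUC_bp × 100

with bp/ap denoting before/after perturbation.  Groups (e.g. AA vs EA
patients) are compared per node with the Mann-Whitney U test, restricted to
nodes whose cohort-level |median ΔAUC| reaches a minimum-change filter
(default 3%), with Benjamini-Hochberg adjustment across the tested nodes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .personalize import PersonalizedModel
from .simulate import (
    SimulationConfig,
    TransitionRates,
    compute_auc,
    detect_steady_state,
    estimate_activity,
    exact_master_equation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationSpec",
    "apply_perturbation",
    "simulate_pair",
    "delta_auc",
    "knockout_table",
    "mann_whitney_u",
    "mann_whitney_exact_p",
    "bh_adjust",
    "compare_groups",
]

#: independent-seed offset for the perturbed run when paired seeds are off
_INDEPENDENT_SEED_OFFSET = 1_000_003

ENGINES = ("gillespie", "exact")


@dataclass(frozen=True)
class PerturbationSpec:
    """Node forcings applied on top of a personalized model, e.g. {"AR": 0}."""

    forced_nodes: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "forced_nodes", dict(self.forced_nodes))
        if not self.forced_nodes:
            logger.debug("empty perturbation: before and after runs coincide")
        for node, v in self.forced_nodes.items():
            if v not in (0, 1):
                raise ValueError(f"perturbation value for {node!r} must be 0 or 1")


def apply_perturbation(model: PersonalizedModel, spec: PerturbationSpec) -> PersonalizedModel:
    """Model with the perturbation's forcings overriding the patient's own."""
    missing = set(spec.forced_nodes) - set(model.network.nodes)
    if missing:
        raise ValueError(f"perturbation targets absent from network: {sorted(missing)}")
    forcings = dict(model.forcings)
    forcings.update(spec.forced_nodes)
    up = {n: r for n, r in model.rates.up.items() if n not in forcings}
    down = {n: r for n, r in model.rates.down.items() if n not in forcings}
    init = dict(model.initial_p_on)
    for node, v in forcings.items():
        init[node] = float(v)
    return PersonalizedModel(model.network, forcings, TransitionRates(up, down), init)


def _activity(model, config, engine):
    if engine == "gillespie":
        return estimate_activity(model, config)
    if engine == "exact":
        return exact_master_equation(model, config)
    raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")


def simulate_pair(
    model: PersonalizedModel,
    spec: PerturbationSpec,
    config: SimulationConfig,
    engine: str = "gillespie",
    paired_seeds: bool = True,
) -> pd.DataFrame:
    """Baseline and perturbed AUCs per node.

    With ``paired_seeds`` both runs use the same random streams (common
    random numbers), reducing the Monte Carlo variance of ΔAUC.  A
    not-reached steady state is recorded, not fatal.
    """
    perturbed = apply_perturbation(model, spec)
    config_ap = config if paired_seeds else replace(config, seed=config.seed + _INDEPENDENT_SEED_OFFSET)
    curves_bp = _activity(model, config, engine)
    curves_ap = _activity(perturbed, config_ap, engine)
    rows = []
    for node in model.network.nodes:
        ss_bp = detect_steady_state(curves_bp[node], config)
        ss_ap = detect_steady_state(curves_ap[node], config_ap)
        if not (ss_bp.reached and ss_ap.reached):
            # recorded in the steady_bp/steady_ap output columns; not fatal
            logger.debug("node %s did not reach steady state within t_max", node)
        rows.append(
            {
                "node": node,
                "auc_bp": compute_auc(curves_bp[node]),
                "auc_ap": compute_auc(curves_ap[node]),
                "steady_bp": ss_bp.reached,
                "steady_ap": ss_ap.reached,
            }
        )
    return pd.DataFrame(rows)


def delta_auc(auc_bp: float, auc_ap: float, floor: float = 1e-6) -> float:
    """Relative AUC change in percent; NaN (undefined) when auc_bp < floor.

    The floor guards the division for nodes that are essentially OFF before
    the perturbation.
    """
    if auc_bp < 0 or auc_ap < 0:
        raise ValueError("AUC values must be non-negative")
    if auc_bp < floor:
        return float("nan")
    return (auc_ap - auc_bp) / auc_bp * 100.0


def knockout_table(
    models: Mapping[str, PersonalizedModel],
    spec: PerturbationSpec,
    config: SimulationConfig,
    engine: str = "gillespie",
    floor: Optional[float] = None,
    paired_seeds: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-node ΔAUC table for a cohort of personalized models.

    ``floor`` defaults to 10⁻³·t_max (ΔAUC undefined below it).
    """
    if floor is None:
        floor = 1e-3 * config.t_max
    frames = []
    for sample, model in models.items():
        df = simulate_pair(model, spec, config, engine=engine, paired_seeds=paired_seeds)
        df.insert(0, "sample", sample)
        df["delta_pct"] = [
            delta_auc(bp, ap, floor) for bp, ap in zip(df["auc_bp"], df["auc_ap"])
        ]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Mann-Whitney U (of the first group) and two-sided p.

    Exact p by enumeration when n_a·n_b ≤ 400 and there are no ties,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_exact_p(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided p by full enumeration of group labelings (oracle; no ties)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size < pooled.size:
        raise ValueError("exact enumeration requires tie-free data")
    n_a = a.size
    u_obs = sum(1 for x in a for y in b if x > y)
    n = pooled.size
    u_values = []
    for combo in itertools.combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        xa, xb = pooled[sel], pooled[~sel]
        u_values.append(sum(1 for x in xa for y in xb if x > y))
    u_values = np.array(u_values)
    mean_u = n_a * (n - n_a) / 2.0
    # two-sided: as or more extreme in |U - E[U]|
    p = np.mean(np.abs(u_values - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    records: pd.DataFrame,
    metadata: Mapping[str, str] | pd.DataFrame,
    threshold_pct: float = 3.0,
    alpha: float = 0.05,
    pathway_groups: Optional[Mapping[str, str]] = None,
    filter_stat: str = "median",
) -> pd.DataFrame:
    """Per-node two-group comparison of ΔAUC with filter + Mann-Whitney + BH.

    A node is tested iff the larger of the two group |``filter_stat``
    ΔAUC| values is ≥ ``threshold_pct`` (alternatives: "mean", "any" —
    any single sample).  BH runs over the tested nodes only; significance
    is adjusted p < alpha.  Undefined (NaN) ΔAUC values are dropped per
    node.  Exactly two group labels must be present.
    """
    if filter_stat not in ("median", "mean", "any"):
        raise ValueError("filter_stat must be 'median', 'mean' or 'any'")
    if isinstance(metadata, pd.DataFrame):
        group_of = dict(zip(metadata["sample"].astype(str), metadata["group"].astype(str)))
    else:
        group_of = {str(k): str(v) for k, v in metadata.items()}
    df = records.copy()
    df["group"] = df["sample"].astype(str).map(group_of)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "sample"].unique())
        raise ValueError(f"samples missing from metadata: {missing}")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(
            f"exactly two groups required, found {groups}; run pairwise comparisons"
        )
    ga, gb = groups

    rows = []
    for node, sub in df.groupby("node", sort=False):
        sub = sub.dropna(subset=["delta_pct"])
        va = sub.loc[sub["group"] == ga, "delta_pct"].to_numpy()
        vb = sub.loc[sub["group"] == gb, "delta_pct"].to_numpy()
        med_a = float(np.median(va)) if va.size else float("nan")
        med_b = float(np.median(vb)) if vb.size else float("nan")
        if va.size == 0 or vb.size == 0:
            tested = False
        elif filter_stat == "median":
            tested = max(abs(med_a), abs(med_b)) >= threshold_pct
        elif filter_stat == "mean":
            tested = max(abs(va.mean()), abs(vb.mean())) >= threshold_pct
        else:
            tested = bool(np.any(np.abs(np.concatenate([va, vb])) >= threshold_pct))
        row = {
            "node": node,
            "pathway": pathway_groups.get(node) if pathway_groups else None,
            "group_a": ga,
            "group_b": gb,
            "median_delta_a": med_a,
            "median_delta_b": med_b,
            "n_a": int(va.size),
            "n_b": int(vb.size),
            "tested": tested,
            "u_statistic": float("nan"),
            "p_value": float("nan"),
            "adjusted_p": float("nan"),
            "significant": False,
        }
        if tested:
            u, p = mann_whitney_u(va, vb)
            row["u_statistic"], row["p_value"] = u, p
        rows.append(row)

    out = pd.DataFrame(rows)
    tested_mask = out["tested"].to_numpy()
    if tested_mask.any():
        adj = bh_adjust(out.loc[tested_mask, "p_value"].to_numpy())
        out.loc[tested_mask, "adjusted_p"] = adj
        out.loc[tested_mask, "significant"] = adj < alpha
    return out
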
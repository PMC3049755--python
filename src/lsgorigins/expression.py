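"""Expression breadth, level distributions and stress-response enrichment.

Present/absent calls are collapsed per tissue (present in any replicate =
present), breadth is the number of tissues a gene is expressed in, and
per-contrast differential-expression sets feed a hypergeometric test for
LSG enrichment among up- and down-regulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ThresholdConfig, ValidationError, median_siqr, share_pct
from .origins import hypergeometric_enrichment


@dataclass
class EnrichmentResult:
    contrast: str
    tissue: str
    time_point: str
    direction: str  # "up" | "down"
    k: int  # DE LSGs
    K: int  # LSGs tested
    n: int  # DE genes
    N: int  # genes tested
    p_value: float
    enriched: bool


def collapse_calls(
    calls: pd.DataFrame, sample_tissue: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a genes x samples boolean call matrix to tissue presence.

    A gene is present in a tissue when present in any replicate of that
    tissue (logical OR, replicate-order invariant and idempotent).
    Returns the genes x tissues presence matrix and per-gene breadth.
    """
    missing = [s for s in calls.columns if s not in sample_tissue]
    if missing:
        raise ValidationError(f"samples without tissue labels: {missing[:5]}")
    tissues = pd.Series({s: sample_tissue[s] for s in calls.columns})
    presence = calls.astype(bool).T.groupby(tissues).any().T
    breadth = presence.sum(axis=1)
    breadth.name = "breadth"
    return presence, breadth


def breadth_comparison(
    breadth: pd.Series, lsg_labels: Mapping[str, bool], max_b: int | None = None
) -> pd.DataFrame:
    """Share of each group expressed in <= b tissues, plus medians.

    One row per (group, b); the final rows carry the group medians with
    semi-interquartile ranges.  Empty groups report missing shares.
    """
    is_lsg = breadth.index.to_series().map(lambda g: bool(lsg_labels.get(g, False)))
    groups = {"LSG": breadth[is_lsg], "non-LSG": breadth[~is_lsg]}
    if max_b is None:
        max_b = int(breadth.max()) if len(breadth) else 0
    rows = []
    for label, values in groups.items():
        for b in range(max_b + 1):
            rows.append(
                {
                    "group": label,
                    "max_tissues": b,
                    "count": int((values <= b).sum()),
                    "denominator": len(values),
                    "share_pct": share_pct(int((values <= b).sum()), len(values)),
                }
            )
    summary = []
    for label, values in groups.items():
        stats_ = median_siqr(values.to_list())
        summary.append(
            {
                "group": label,
                "median_breadth": None if stats_ is None else stats_[0],
                "siqr": None if stats_ is None else stats_[1],
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["medians"] = pd.DataFrame(summary)
    return table


def expression_distributions(
    expression: pd.DataFrame,
    presence: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    lsg_labels: Mapping[str, bool],
) -> pd.DataFrame:
    """Per-tissue median expression of present genes, split by group.

    ``expression`` is a genes x samples log2 matrix; per gene and tissue
    the median over that tissue's replicates is taken first, then the
    group median (with SIQR) over genes called present in the tissue.
    Tissues with no present genes in a group yield missing entries.
    """
    tissues = pd.Series({s: sample_tissue[s] for s in expression.columns})
    per_tissue = expression.T.groupby(tissues).median().T
    rows = []
    for tissue in sorted(per_tissue.columns):
        for label, want in (("LSG", True), ("non-LSG", False)):
            genes = [
                g
                for g in per_tissue.index
                if bool(lsg_labels.get(g, False)) == want
                and tissue in presence.columns
                and bool(presence.loc[g, tissue])
            ]
            stats_ = median_siqr(per_tissue.loc[genes, tissue].to_list())
            rows.append(
                {
                    "tissue": tissue,
                    "group": label,
                    "n_present": len(genes),
                    "median_log2": None if stats_ is None else round(stats_[0], 4),
                    "siqr": None if stats_ is None else round(stats_[1], 4),
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_de(
    de_table: pd.DataFrame | None = None,
    treatment: pd.DataFrame | None = None,
    control: pd.DataFrame | None = None,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets for one contrast.

    Table mode expects columns (gene, log2fc, adj_p).  Raw mode runs an
    unpaired two-sample t test per gene on replicate matrices and adjusts
    with Benjamini-Hochberg — a plain stand-in for a moderated model, so
    real studies should supply the table.  A gene is up when
    ``adj_p < de_adj_p`` and ``log2fc > de_min_abs_log2fc``; down
    symmetrically.  The two sets are disjoint by construction.
    """
    if de_table is not None:
        required = {"gene", "log2fc", "adj_p"}
        if not required <= set(de_table.columns):
            raise ValidationError(
                f"DE table needs columns {sorted(required)}, has "
                f"{sorted(de_table.columns)}"
            )
        table = de_table
    else:
        if treatment is None or control is None:
            raise ValidationError("raw mode needs treatment and control matrices")
        if treatment.shape[1] < 2 or control.shape[1] < 2:
            raise ValidationError("raw mode needs >= 2 replicates per arm")
        genes = treatment.index
        log2fc = treatment.mean(axis=1) - control.loc[genes].mean(axis=1)
        t_res = stats.ttest_ind(
            treatment.to_numpy(), control.loc[genes].to_numpy(), axis=1
        )
        p_raw = np.nan_to_num(t_res.pvalue, nan=1.0)
        table = pd.DataFrame(
            {"gene": genes, "log2fc": log2fc.to_numpy(), "adj_p": bh_adjust(p_raw)}
        )
    up = set(
        table.loc[
            (table["adj_p"] < thresholds.de_adj_p)
            & (table["log2fc"] > thresholds.de_min_abs_log2fc),
            "gene",
        ]
    )
    down = set(
        table.loc[
            (table["adj_p"] < thresholds.de_adj_p)
            & (table["log2fc"] < -thresholds.de_min_abs_log2fc),
            "gene",
        ]
    )
    return up, down


@dataclass
class ContrastSets:
    contrast: str
    tissue: str
    time_point: str
    up: set[str]
    down: set[str]
    universe: set[str]


def lsg_stress_enrichment(
    contrasts: Sequence[ContrastSets],
    lsg_labels: Mapping[str, bool],
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> tuple[list[EnrichmentResult], dict[str, int]]:
    """Hypergeometric LSG enrichment per contrast/tissue/time/direction.

    Also returns union counts of up-, down- and either-direction DE LSGs
    across all contrasts.
    """
    results: list[EnrichmentResult] = []
    union_up: set[str] = set()
    union_down: set[str] = set()
    for contrast in contrasts:
        universe = contrast.universe
        lsgs = {g for g in universe if lsg_labels.get(g, False)}
        for direction, de_set in (("up", contrast.up), ("down", contrast.down)):
            if not de_set <= universe:
                raise ValidationError(
                    f"{contrast.contrast}: DE set not contained in universe"
                )
            k = len(de_set & lsgs)
            p = hypergeometric_enrichment(
                k, len(lsgs), len(de_set), len(universe), tail="upper"
            )
            results.append(
                EnrichmentResult(
                    contrast=contrast.contrast,
                    tissue=contrast.tissue,
                    time_point=contrast.time_point,
                    direction=direction,
                    k=k,
                    K=len(lsgs),
                    n=len(de_set),
                    N=len(universe),
                    p_value=p,
                    enriched=p < thresholds.enrichment_p,
                )
            )
        union_up |= contrast.up & lsgs
        union_down |= contrast.down & lsgs
    counts = {
        "lsg_up": len(union_up),
        "lsg_down": len(union_down),
        "lsg_both": len(union_up & union_down),
        "lsg_either": len(union_up | union_down),
    }
    return results, counts


def responsive_origin_breakdown(
    responsive_lsgs: set[str],
    assignments: Mapping[str, "object"],
) -> pd.DataFrame:
    """Origin-mechanism shares among stress-responsive LSGs."""
    counts: dict[str, int] = {}
    for gene_id in responsive_lsgs:
        assignment = assignments.get(gene_id)
        mechanism = (
            assignment.primary_mechanism.value if assignment is not None else "unknown"
        )
        counts[mechanism] = counts.get(mechanism, 0) + 1
    total = len(responsive_lsgs)
    return pd.DataFrame(
        [
            {
                "mechanism": mech,
                "count": counts[mech],
                "denominator": total,
                "share_pct": share_pct(counts[mech], total),
            }
            for mech in sorted(counts)
        ]
    )
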
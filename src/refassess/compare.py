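"""Head-to-head statistics, cherry-picking and molecular-replacement viability.

Group pairs are compared with a one-tailed Wilcoxon signed-rank test on
paired Δ_Q values (exact null distribution up to n = 25 paired differences,
continuity-corrected normal approximation above; zero differences dropped,
tied magnitudes average-ranked), at a fixed significance level with no
multiple-testing correction.

Cherry-picking re-scores all submissions of a target in one pooled
population and asks which of a group's up-to-five entries would have scored
best a posteriori — and how often that entry was in fact labelled model 1.

Molecular-replacement viability thresholds externally computed Phaser LLG
scores: a model with LLG > 60 almost always yields an automated MR solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from refassess.ranking import (
    HIGHER_BETTER,
    METRICS,
    ModelRecord,
    ZRecord,
    compute_zrecords,
    per_target_stats,
)

DEFAULT_ALPHA = 0.01
EXACT_MAX_N = 25
MR_LLG_THRESHOLD = 60.0


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    metric: str
    n: int
    p_value: float
    significant: bool


def _signed_rank_p(diffs: np.ndarray) -> tuple[float, int]:
    """One-tailed p-value for 'positive differences dominate'.

    Returns (p, n_nonzero).  Exact enumeration of the signed-rank null via
    a generating-function convolution for n ≤ 25 (ranks doubled so tied
    average ranks stay on an integer lattice); otherwise normal
    approximation with continuity correction using the tie-adjusted rank
    variance.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0, 0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # distribution of doubled W+ over all 2^n sign assignments
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        w2 = int(np.rint(2 * w_plus))
        p = dist[w2:].sum() / 2.0**n
        return float(p), n
    mean = ranks.sum() / 2.0
    var = float(np.sum(ranks**2)) / 4.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z)), n


def wilcoxon_one_tailed(
    deltas_a: np.ndarray,
    deltas_b: np.ndarray,
    better_is: int = 1,
    alpha: float = DEFAULT_ALPHA,
    group_a: str = "A",
    group_b: str = "B",
    metric: str = "",
) -> PairwiseResult:
    """Test the null that group A does not perform better than group B on
    their paired per-target Δ values.

    ``better_is`` is +1 when larger Δ is better (GDT-HA, GDC-SC, SphGr) and
    −1 when smaller is better (RMSD, MP).
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    d = (a - b) * better_is
    p, n = _signed_rank_p(d)
    return PairwiseResult(group_a, group_b, metric, n, p, significant=p < alpha)


def head_to_head_counts(
    top_groups: list[str],
    records: list[ModelRecord],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """For each group in ``top_groups`` and each metric, the number of other
    listed groups it outperforms significantly on their common targets.

    Pairs sharing no target (or no nonzero difference) simply contribute no
    win.  Groups outside ``top_groups`` are never considered.
    """
    deltas: dict[str, dict[str, dict[str, float]]] = {}
    for r in records:
        if r.group in top_groups:
            for q in METRICS:
                if r.delta[q] is not None:
                    deltas.setdefault(r.group, {}).setdefault(q, {})[r.target] = r.delta[q]
    counts = {g: {q: 0 for q in METRICS} for g in top_groups}
    for q in METRICS:
        sign = 1 if HIGHER_BETTER[q] else -1
        for ga in top_groups:
            for gb in top_groups:
                if ga == gb:
                    continue
                da = deltas.get(ga, {}).get(q, {})
                db = deltas.get(gb, {}).get(q, {})
                common = sorted(set(da) & set(db))
                if not common:
                    continue
                res = wilcoxon_one_tailed(
                    [da[t] for t in common],
                    [db[t] for t in common],
                    better_is=sign,
                    alpha=alpha,
                    group_a=ga,
                    group_b=gb,
                    metric=q,
                )
                if res.significant:
                    counts[ga][q] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "group"
    return df.reset_index()


@dataclass
class CherryPick:
    target: str
    group: str
    chosen_index: int
    pooled_sp: float
    was_model1: bool
    model1_pooled_sp: float | None = None


def pooled_zrecords(records: list[ModelRecord]) -> list[ZRecord]:
    """Re-score all submissions (every group, every model index) with
    per-target statistics estimated from that pooled population."""
    stats = per_target_stats(records)
    return compute_zrecords(records, stats=stats)


def cherry_pick(pooled: list[ZRecord]) -> list[CherryPick]:
    """A-posteriori best entry per (target, group) under pooled scoring.

    Ties on the pooled S_p go to the lowest model index (the submitter's own
    ordering).
    """
    by_tg: dict[tuple[str, str], list[ZRecord]] = {}
    for r in pooled:
        by_tg.setdefault((r.target, r.group), []).append(r)
    picks = []
    for (target, group), recs in sorted(by_tg.items()):
        best = max(recs, key=lambda r: (r.s_p, -r.model_index))
        model1 = next((r for r in recs if r.model_index == 1), None)
        picks.append(
            CherryPick(
                target=target,
                group=group,
                chosen_index=best.model_index,
                pooled_sp=best.s_p,
                was_model1=best.model_index == 1,
                model1_pooled_sp=model1.s_p if model1 else None,
            )
        )
    return picks


def model1_identification_rate(
    picks: list[CherryPick],
    group: str,
    qualifying_targets: set[str] | None = None,
) -> float:
    """Percentage of qualifying targets on which the group's model 1 would
    have been cherry-picked a posteriori.

    ``qualifying_targets`` restricts to targets where the group submitted a
    full set of five models (callers decide eligibility).
    """
    sel = [
        p
        for p in picks
        if p.group == group
        and (qualifying_targets is None or p.target in qualifying_targets)
    ]
    if not sel:
        raise ValueError(f"no qualifying target for group {group}")
    return 100.0 * sum(p.was_model1 for p in sel) / len(sel)


def load_printed_mr_table() -> pd.DataFrame:
    """The 13 printed starting/best LLG pairs shipped with the package."""
    text = resources.files("refassess").joinpath("data/casp10_mr_llg.tsv").read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        target, s, best_id, b = line.split("\t")
        rows.append({"target": target, "starting_llg": float(s), "best_model_id": best_id, "best_llg": float(b)})
    return pd.DataFrame(rows)


def mr_viability(
    starting_llg: dict[str, float],
    model_llg: list[dict],
    threshold: float = MR_LLG_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Molecular-replacement viability per target and per group.

    ``model_llg`` rows need keys: target, group, model_id, llg.  Viability is
    strict (LLG > threshold).  Per target: starting viable?, best-model
    viable?, rescued? (starting below threshold, best above).  Per group:
    number of targets whose best submission from that group is viable, and
    the mean ΔLLG of that best versus the starting model.  Targets lacking a
    starting LLG are skipped.
    """
    df = pd.DataFrame(model_llg)
    target_rows = []
    skipped = []
    for target, sub in df.groupby("target"):
        s = starting_llg.get(target)
        if s is None:
            skipped.append(target)
            continue
        best = sub.loc[sub["llg"].idxmax()]
        target_rows.append(
            {
                "target": target,
                "starting_llg": s,
                "best_model_id": best["model_id"],
                "best_llg": best["llg"],
                "starting_viable": s > threshold,
                "best_viable": best["llg"] > threshold,
                "rescued": (s < threshold) and (best["llg"] > threshold),
            }
        )
    per_target = pd.DataFrame(target_rows)
    group_rows = []
    for group, sub in df.groupby("group"):
        n_viable = 0
        dllg = []
        for target, tsub in sub.groupby("target"):
            s = starting_llg.get(target)
            if s is None:
                continue
            best = tsub["llg"].max()
            if best > threshold:
                n_viable += 1
            dllg.append(best - s)
        group_rows.append(
            {
                "group": group,
                "n_viable_targets": n_viable,
                "mean_delta_llg": float(np.mean(dllg)) if dllg else np.nan,
            }
        )
    per_group = pd.DataFrame(group_rows).sort_values(
        ["n_viable_targets", "mean_delta_llg"], ascending=False
    ).reset_index(drop=True)
    per_target.attrs["skipped_targets"] = skipped
    return per_target, per_group
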
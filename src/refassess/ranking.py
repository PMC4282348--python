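"""Δ-scores, target-wise robust Z-scores, clipping, S_p and group ranking.

Every submission p is scored by its change Δ_Q(p) = Q(p) − Q(s) relative to
the starting model s, for each quality measure Q.  Per target, the Δ_Q of
all assessed model-1 submissions are converted to robust Z-scores,
(Δ − median)/MAD, so that scores are comparable across targets.  Negative
Z for higher-better measures (GDT-HA, GDC-SC, SphGr) and positive Z for
lower-better ones (RMSD, MP) are clipped to zero — adventurous failures are
not punished — and combined into

    S_p = Z_GDT-HA + Z_GDC-SC + Z_SphGr − Z_RMSD − Z_MP  ≥ 0.

Groups are ranked by their median S_p over predicted targets, with an
eligibility threshold on the number of targets attempted, alongside a naive
baseline that resubmits the starting model unchanged (scored against the
participants' statistics without entering them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRICS = ("gdt_ha", "rmsd", "gdc_sc", "sphgr", "mp")
HIGHER_BETTER = {"gdt_ha": True, "rmsd": False, "gdc_sc": True, "sphgr": True, "mp": False}

DEFAULT_MIN_TARGETS = 23
#: multiplying the plain MAD by 1.4826 makes it consistent with the normal
#: SD; the ranking uses the plain MAD but the constant is configurable
DEFAULT_MAD_CONSTANT = 1.0

NAIVE_GROUP_ID = "naive"


@dataclass
class ModelRecord:
    """One assessed submission: its Δ_Q values plus identity."""

    target: str
    group: str
    model_index: int
    delta: dict[str, float | None]  # per metric; absent MP propagates as None


@dataclass
class ZRecord:
    target: str
    group: str
    model_index: int
    z_raw: dict[str, float | None]
    z: dict[str, float]  # clipped; absent MP contributes 0
    s_p: float
    mp_absent: bool = False


def delta_scores(mv_model, mv_start) -> dict[str, float | None]:
    """Componentwise Δ_Q = Q(model) − Q(starting); absent MP stays absent."""
    dm, ds = mv_model.as_dict(), mv_start.as_dict()
    out: dict[str, float | None] = {}
    for q in METRICS:
        if dm[q] is None or ds[q] is None:
            out[q] = None
        else:
            out[q] = dm[q] - ds[q]
    return out


def robust_stats(
    values: np.ndarray,
    use_mean_sd: bool = False,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
) -> tuple[float, float]:
    """(center, scale) for Z-scoring; scale 0 signals a degenerate target.

    Default: median and MAD (median absolute deviation, no consistency
    constant).  MAD = 0 falls back to the sample standard deviation; if that
    is also 0 the scale is 0 and all Z-scores are defined as 0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to standardize")
    if use_mean_sd:
        return float(values.mean()), float(values.std(ddof=1))
    center = float(np.median(values))
    mad = float(np.median(np.abs(values - center))) * mad_constant
    if mad > 0:
        return center, mad
    sd = float(values.std(ddof=1))
    return center, sd


def robust_z(values: np.ndarray, **kwargs) -> np.ndarray:
    """Robust Z-scores (Δ − median)/MAD of one target's values."""
    values = np.asarray(values, dtype=float)
    center, scale = robust_stats(values, **kwargs)
    if scale == 0:
        return np.zeros_like(values)
    return (values - center) / scale


def clip_z(metric: str, z: float) -> float:
    """Clip to zero the unrewarded tail: negative Z for higher-better
    measures, positive Z for lower-better ones."""
    if HIGHER_BETTER[metric]:
        return max(z, 0.0)
    return min(z, 0.0)


def clip_and_combine(
    z_raw: dict[str, float | None], target: str = "", group: str = "", model_index: int = 1
) -> ZRecord:
    """Apply the sign-aware clipping and combine into S_p.

    An absent MP Z contributes 0 to S_p and is flagged.
    """
    z: dict[str, float] = {}
    mp_absent = False
    for q in METRICS:
        raw = z_raw.get(q)
        if raw is None:
            z[q] = 0.0
            if q == "mp":
                mp_absent = True
        else:
            z[q] = clip_z(q, raw)
    s_p = z["gdt_ha"] + z["gdc_sc"] + z["sphgr"] - z["rmsd"] - z["mp"]
    return ZRecord(
        target=target, group=group, model_index=model_index,
        z_raw=dict(z_raw), z=z, s_p=s_p, mp_absent=mp_absent,
    )


def per_target_stats(
    records: list[ModelRecord], **kwargs
) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-target, per-metric (center, scale) over the records' Δ values.

    Records with an absent value for a metric are excluded from that
    metric's statistics.
    """
    by_target: dict[str, list[ModelRecord]] = {}
    for r in records:
        by_target.setdefault(r.target, []).append(r)
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for target, recs in by_target.items():
        stats[target] = {}
        for q in METRICS:
            vals = [r.delta[q] for r in recs if r.delta[q] is not None]
            if len(vals) >= 2:
                stats[target][q] = robust_stats(np.array(vals), **kwargs)
    return stats


def compute_zrecords(
    records: list[ModelRecord],
    stats: dict[str, dict[str, tuple[float, float]]] | None = None,
    **kwargs,
) -> list[ZRecord]:
    """Z-score every record against per-target statistics (computed from the
    records themselves unless supplied, e.g. for pooled re-scoring)."""
    if stats is None:
        stats = per_target_stats(records, **kwargs)
    out = []
    for r in records:
        z_raw: dict[str, float | None] = {}
        for q in METRICS:
            st = stats.get(r.target, {}).get(q)
            if st is None or r.delta[q] is None:
                z_raw[q] = None
            else:
                center, scale = st
                z_raw[q] = 0.0 if scale == 0 else (r.delta[q] - center) / scale
        out.append(clip_and_combine(z_raw, r.target, r.group, r.model_index))
    return out


def naive_baseline(
    target: str, stats: dict[str, dict[str, tuple[float, float]]]
) -> ZRecord:
    """Score the starting model itself (all Δ_Q = 0) against the
    participants' statistics for one target; the naive entry never enters
    those statistics."""
    z_raw: dict[str, float | None] = {}
    for q in METRICS:
        st = stats.get(target, {}).get(q)
        if st is None:
            z_raw[q] = None
        else:
            center, scale = st
            z_raw[q] = 0.0 if scale == 0 else (0.0 - center) / scale
    return clip_and_combine(z_raw, target, NAIVE_GROUP_ID, 1)


def group_ranking(
    zrecords: list[ZRecord],
    min_targets: int = DEFAULT_MIN_TARGETS,
    group_types: dict[str, str] | None = None,
    naive_records: list[ZRecord] | None = None,
) -> pd.DataFrame:
    """Median S_p per group over predicted targets, eligible groups only,
    sorted descending; the naive baseline row (if given) is appended for
    reference and exempt from the eligibility threshold."""
    rows = []
    by_group: dict[str, list[ZRecord]] = {}
    for r in zrecords:
        by_group.setdefault(r.group, []).append(r)
    for g, recs in by_group.items():
        n = len({r.target for r in recs})
        rows.append(
            {
                "group": g,
                "type": (group_types or {}).get(g, "unknown"),
                "n_targets": n,
                "median_sp": float(np.median([r.s_p for r in recs])),
                "eligible": n >= min_targets,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or not df["eligible"].any():
        raise ValueError("no eligible groups")
    df = df[df["eligible"]].drop(columns="eligible")
    df = df.sort_values("median_sp", ascending=False, kind="mergesort").reset_index(drop=True)
    if naive_records:
        naive_row = {
            "group": NAIVE_GROUP_ID,
            "type": "baseline",
            "n_targets": len({r.target for r in naive_records}),
            "median_sp": float(np.median([r.s_p for r in naive_records])),
        }
        df = pd.concat([df, pd.DataFrame([naive_row])], ignore_index=True)
    return df


def aggregate_improvement_stats(records: list[ModelRecord]) -> pd.DataFrame:
    """Per metric: percentage of models strictly better / strictly worse /
    tied with the starting model, sign convention metric-aware."""
    rows = []
    for q in METRICS:
        vals = np.array([r.delta[q] for r in records if r.delta[q] is not None], dtype=float)
        if len(vals) == 0:
            rows.append({"metric": q, "pct_better": np.nan, "pct_worse": np.nan, "pct_tied": np.nan, "n": 0})
            continue
        sign = 1.0 if HIGHER_BETTER[q] else -1.0
        better = np.sum(sign * vals > 0)
        worse = np.sum(sign * vals < 0)
        tied = np.sum(vals == 0)
        n = len(vals)
        rows.append(
            {
                "metric": q,
                "pct_better": 100.0 * better / n,
                "pct_worse": 100.0 * worse / n,
                "pct_tied": 100.0 * tied / n,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
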
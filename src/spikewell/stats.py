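"""Two-tier nonparametric group statistics on well-level features.

Tier 1 — longitudinal: for each recording day a two-sided Mann-Whitney U
(MWU) test compares the two conditions' well values; the per-day p-values
over an analysis window (default DIV 8-16) combine via Fisher's method
(chi2 = -2 * sum(ln p), df = 2k).

Tier 2 — pooled: each well's values over the window reduce to a single
observation (default: the well's mean over available days), a two-sided
MWU compares the two well sets, and significance is calibrated by
permuting the condition labels across wells (group sizes preserved;
default 10,000 permutations).  The empirical p-value uses the
add-one correction ``(1 + #{p_perm <= p_obs}) / (n_perm + 1)``, so its
attainable minimum at 10,000 permutations is 1/10,001 (reported in
practice as p < 0.0001); ties between permuted and observed p-values
count against the observed one (the conservative choice).

The permutation unit is the well — the independent experimental unit —
which keeps the null exchangeable even when observations within a well
are correlated across days.  A ``concat`` reducer (well-day observations,
labels still permuted per well) is available as an alternative reading of
"combining" a well's values.

The MWU p-value inside the permutation loop is computed from rank sums
with the tie-corrected, continuity-corrected normal approximation for
both the observed and the permuted labelings, so observed and null
p-values are always on the same scale.  The standalone :func:`mwu_test`
switches to exact enumeration over all label splits when both groups have
at most 8 observations (the enumeration handles ties, so two identical
samples give p = 1 exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GroupAssignment

__all__ = [
    "MWUResult",
    "FisherResult",
    "GroupComparison",
    "mwu_test",
    "fisher_combine",
    "permutation_test",
    "per_div_series",
    "compare_groups",
]

EXACT_MAX_N = 8


@dataclass(frozen=True)
class MWUResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided p-value
    method: str  # "exact" | "asymptotic"


def _clean(values: Sequence[float]) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[~np.isnan(a)]


def _exact_mwu(a: np.ndarray, b: np.ndarray) -> MWUResult:
    """Two-sided exact MWU by enumeration of all C(N, n_a) label splits.

    Midranks make the enumeration valid under ties; the two-sided p is the
    probability (over splits) of a U at least as far from its null mean
    n_a*n_b/2 as the observed one.
    """
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    mu = n_a * n_b / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    idx = np.fromiter(
        (i for comb in combinations(range(n_a + n_b), n_a) for i in comb),
        dtype=np.intp,
    ).reshape(-1, n_a)
    u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
    p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
    return MWUResult(u=float(u_obs), p=p, method="exact")


def mwu_test(a: Sequence[float], b: Sequence[float]) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    Missing values are dropped; each group needs >= 2 remaining values.
    Exact enumeration is used when both groups have <= 8 observations,
    otherwise the tie-corrected normal approximation (with continuity
    correction).
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 non-missing values (got {len(a)} and {len(b)})"
        )
    if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
        return _exact_mwu(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MWUResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")


@dataclass(frozen=True)
class FisherResult:
    chi2: float
    df: int
    p: float


def fisher_combine(p_values: Sequence[float]) -> FisherResult:
    """Fisher's combined probability: chi2 = -2*sum(ln p) on 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return FisherResult(chi2=chi2, df=df, p=float(sps.chi2.sf(chi2, df)))


# --------------------------------------------------------------------------
# permutation machinery


def _rank_p_from_wells(
    rank_sum_a: np.ndarray,
    n_a_obs: np.ndarray,
    n_total_obs: int,
    tie_term: float,
) -> np.ndarray:
    """Vectorised two-sided MWU p from group-A rank sums.

    ``tie_term`` is sum(t^3 - t) over tie groups of the pooled sample.
    """
    n_b_obs = n_total_obs - n_a_obs
    u1 = rank_sum_a - n_a_obs * (n_a_obs + 1) / 2.0
    mu = n_a_obs * n_b_obs / 2.0
    var = (
        n_a_obs
        * n_b_obs
        / 12.0
        * ((n_total_obs + 1) - tie_term / (n_total_obs * (n_total_obs - 1)))
    )
    var = np.maximum(var, 1e-300)
    z = (np.abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = np.maximum(z, 0.0)
    return np.minimum(2.0 * sps.norm.sf(z), 1.0)


def _well_observations(
    feature_table: pd.DataFrame,
    feature: str,
    window: tuple[int, int],
    reducer: str,
) -> dict[str, np.ndarray]:
    """Per-well observation vectors for the pooled-window test."""
    lo, hi = window
    sub = feature_table[(feature_table["div"] >= lo) & (feature_table["div"] <= hi)]
    if sub.empty:
        raise ValueError(f"no feature rows inside DIV window {lo}-{hi}")
    obs: dict[str, np.ndarray] = {}
    for well, wsub in sub.groupby("well_id"):
        vals = wsub[feature].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        if reducer == "mean":
            obs[str(well)] = np.array([vals.mean()])
        elif reducer == "concat":
            obs[str(well)] = vals
        else:
            raise ValueError(f"unknown reducer {reducer!r} (use 'mean' or 'concat')")
    return obs


@dataclass
class GroupComparison:
    """Full two-tier comparison of one feature between two conditions."""

    feature: str
    window: tuple[int, int]
    conditions: tuple[str, str]
    n_per_group: tuple[int, int]
    per_div_p: dict[int, float]
    skipped_divs: list[int]
    fisher_chi2: float
    fisher_df: int
    fisher_p: float
    observed_mwu_p: float
    perm_p: float
    n_perm: int
    seed: int | None

    def to_record(self) -> dict:
        rec = {
            "feature": self.feature,
            "window": f"{self.window[0]}:{self.window[1]}",
            "condition_a": self.conditions[0],
            "condition_b": self.conditions[1],
            "n_a": self.n_per_group[0],
            "n_b": self.n_per_group[1],
            "fisher_chi2": self.fisher_chi2,
            "fisher_df": self.fisher_df,
            "fisher_p": self.fisher_p,
            "observed_mwu_p": self.observed_mwu_p,
            "perm_p": self.perm_p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "per_div_p": {str(d): p for d, p in sorted(self.per_div_p.items())},
            "skipped_divs": list(self.skipped_divs),
        }
        return rec


def _two_conditions(
    assignment: GroupAssignment, wells_present: set[str]
) -> tuple[str, str, list[str], list[str]]:
    conds = assignment.conditions()
    if len(conds) != 2:
        raise ValueError(
            f"exactly two conditions are required for a comparison, got {conds}"
        )
    ca, cb = conds
    wa = [w for w in assignment.wells(ca) if w in wells_present]
    wb = [w for w in assignment.wells(cb) if w in wells_present]
    if len(wa) < 2 or len(wb) < 2:
        raise ValueError(
            f"need >= 2 wells per group after QC/window filtering "
            f"(got {len(wa)} {ca!r}, {len(wb)} {cb!r})"
        )
    return ca, cb, wa, wb


def permutation_test(
    feature_table: pd.DataFrame,
    assignment: GroupAssignment,
    feature: str,
    window: tuple[int, int] = (8, 16),
    n_perm: int = 10_000,
    seed: int | None = None,
    reducer: str = "mean",
) -> GroupComparison:
    """Pooled-window MWU with a well-label permutation null.

    Observed and permuted labelings share one rank-based p computation,
    so ``perm_p`` is the empirical probability (with add-one correction)
    of a null labeling producing an MWU p at most as large as the
    observed one.  Identical seeds give identical results.
    """
    obs = _well_observations(feature_table, feature, window, reducer)
    ca, cb, wa, wb = _two_conditions(assignment, set(obs))

    wells = wa + wb
    n_a_wells = len(wa)
    counts = np.array([len(obs[w]) for w in wells])
    pooled = np.concatenate([obs[w] for w in wells])
    ranks = sps.rankdata(pooled)
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float((t**3 - t).sum())
    n_total = int(counts.sum())
    # per-well rank sums let every permutation reduce to a matrix product
    offsets = np.concatenate(([0], np.cumsum(counts)))
    well_rank_sums = np.array(
        [ranks[offsets[i] : offsets[i + 1]].sum() for i in range(len(wells))]
    )

    def p_for(sel: np.ndarray) -> np.ndarray:
        # sel: boolean matrix (n, n_wells) marking group-A wells
        rs = sel @ well_rank_sums
        na = sel @ counts
        return _rank_p_from_wells(rs, na, n_total, tie_term)

    observed_sel = np.zeros((1, len(wells)), dtype=bool)
    observed_sel[0, :n_a_wells] = True
    p_obs = float(p_for(observed_sel)[0])

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(wells))), axis=1)
    sel = np.zeros((n_perm, len(wells)), dtype=bool)
    np.put_along_axis(sel, order[:, :n_a_wells], True, axis=1)
    p_perm = p_for(sel)
    perm_p = (1.0 + np.sum(p_perm <= p_obs + 1e-12)) / (n_perm + 1.0)

    series = per_div_series(feature_table, assignment, feature, window)
    return GroupComparison(
        feature=feature,
        window=window,
        conditions=(ca, cb),
        n_per_group=(n_a_wells, len(wb)),
        per_div_p=series["per_div_p"],
        skipped_divs=series["skipped_divs"],
        fisher_chi2=series["fisher"].chi2,
        fisher_df=series["fisher"].df,
        fisher_p=series["fisher"].p,
        observed_mwu_p=p_obs,
        perm_p=float(perm_p),
        n_perm=n_perm,
        seed=seed,
    )


def per_div_series(
    feature_table: pd.DataFrame,
    assignment: GroupAssignment,
    feature: str,
    window: tuple[int, int] = (8, 16),
) -> dict:
    """Per-day two-sided MWU p-values plus their Fisher combination.

    Days inside the window with fewer than 2 non-missing wells per group
    are skipped and reported in ``skipped_divs``.
    """
    lo, hi = window
    sub = feature_table[(feature_table["div"] >= lo) & (feature_table["div"] <= hi)]
    if sub.empty:
        raise ValueError(f"no feature rows inside DIV window {lo}-{hi}")
    ca, cb, wa, wb = _two_conditions(assignment, set(sub["well_id"]))
    per_div_p: dict[int, float] = {}
    skipped: list[int] = []
    for div, dsub in sub.groupby("div"):
        by_well = dsub.set_index("well_id")[feature]
        a = _clean([by_well.get(w, math.nan) for w in wa])
        b = _clean([by_well.get(w, math.nan) for w in wb])
        if len(a) < 2 or len(b) < 2:
            skipped.append(int(div))
            continue
        per_div_p[int(div)] = mwu_test(a, b).p
    if not per_div_p:
        raise ValueError(f"no day in window {lo}-{hi} has >= 2 wells per group")
    fisher = fisher_combine(list(per_div_p.values()))
    return {"per_div_p": per_div_p, "skipped_divs": skipped, "fisher": fisher}


def compare_groups(
    feature_table: pd.DataFrame,
    assignment: GroupAssignment,
    features: Sequence[str] | None = None,
    window: tuple[int, int] = (8, 16),
    n_perm: int = 10_000,
    seed: int | None = None,
    reducer: str = "mean",
) -> list[GroupComparison]:
    """Run both statistical tiers for every requested feature.

    Features whose window data are entirely missing are skipped.  Each
    feature draws an independent stream from ``seed`` so results do not
    depend on which other features are requested.
    """
    from .features import ACTIVITY_FEATURES

    feats = list(features) if features is not None else list(ACTIVITY_FEATURES)
    seeds = np.random.SeedSequence(seed).spawn(len(feats)) if seed is not None else [None] * len(feats)
    out = []
    for feat, ss in zip(feats, seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31)) if ss is not None else None
        try:
            out.append(
                permutation_test(
                    feature_table, assignment, feat, window, n_perm, sub_seed, reducer
                )
            )
        except ValueError:
            continue
    return out
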
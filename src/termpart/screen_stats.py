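"""Quantitative analytics for transgene-stability plate screens.

A screen picks primary transformant colonies into 96-well plates and
passages them through serial 7-day subcultures under antibiotic
selection; lines still growing after the final round are "stable" and
are scored for GFP fluorescence.  This module computes:

* transformation efficiency (colonies per µg DNA), mean ± SEM over
  independent experiments with technical replicates averaged first;
* the stability curve (% of initially picked lines viable per round);
* the GFP-positive fraction among final-round viable lines;
* two-tailed Mann-Whitney U tests (exact enumeration or tie-corrected
  normal approximation) between constructs;
* per-construct summary tables for the bubble plot that combines the
  three readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "PlateRecord",
    "TransformationCount",
    "EfficiencyResult",
    "GfpResult",
    "TestResult",
    "ScreenSummary",
    "transformation_efficiency",
    "stability_curve",
    "gfp_fraction",
    "mann_whitney_u",
    "compare_constructs",
    "bubble_summary",
    "summarize_screen",
    "records_from_frame",
    "counts_from_frame",
]


@dataclass(frozen=True)
class PlateRecord:
    """One transformant line's fate through the subculture rounds."""

    line_id: str
    construct: str
    strain: str
    selection: str
    viable_by_round: tuple[bool, ...]
    gfp_positive: bool | None = None
    experiment_id: str = "E1"

    def __post_init__(self) -> None:
        if not self.viable_by_round:
            raise ValueError(f"line {self.line_id}: no viability rounds recorded")
        for earlier, later in zip(self.viable_by_round, self.viable_by_round[1:]):
            if later and not earlier:
                raise ValueError(
                    f"line {self.line_id}: viability is not monotone non-increasing"
                )
        if self.gfp_positive is not None and not self.viable_by_round[-1]:
            raise ValueError(
                f"line {self.line_id}: GFP assessed on a non-viable line"
            )

    @property
    def viable_final(self) -> bool:
        return self.viable_by_round[-1]


@dataclass(frozen=True)
class TransformationCount:
    """Colonies on one selection plate from ``dna_ug`` µg of plasmid."""

    construct: str
    strain: str
    experiment_id: str
    colonies: int
    dna_ug: float = 1.0

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be nonnegative")
        if self.dna_ug <= 0:
            raise ValueError(f"dna_ug must be positive, got {self.dna_ug}")


@dataclass
class EfficiencyResult:
    mean: float
    sem: float
    n_experiments: int
    sem_undefined: bool = False


@dataclass
class GfpResult:
    pct_positive: float | None
    n_viable: int
    n_positive: int
    n_unassessed: int

    @property
    def computable(self) -> bool:
        return self.pct_positive is not None


@dataclass
class TestResult:
    group_x: str
    group_y: str
    U: float
    p_two_tailed: float
    method: str
    alpha: float = 0.05
    skipped: bool = False
    p_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_two_tailed
        return (not self.skipped) and p < self.alpha


@dataclass
class ScreenSummary:
    construct: str
    strain: str
    efficiency_mean: float | None
    efficiency_sem: float | None
    pct_viable_final: float
    pct_gfp_positive: float | None
    n_lines: int
    n_experiments: int


def transformation_efficiency(counts: Sequence[TransformationCount]) -> EfficiencyResult:
    """Mean ± SEM of colonies/µg over independent experiments.

    Technical replicates (multiple plates within one ``experiment_id``)
    are averaged first; SEM = sd/sqrt(n_experiments).  With a single
    experiment the SEM is reported as 0 and flagged undefined.
    """
    if not counts:
        raise ValueError("no transformation counts given")
    per_exp: dict[str, list[float]] = {}
    for c in counts:
        per_exp.setdefault(c.experiment_id, []).append(c.colonies / c.dna_ug)
    exp_means = np.array([np.mean(v) for v in per_exp.values()])
    n = len(exp_means)
    if n == 1:
        return EfficiencyResult(float(exp_means[0]), 0.0, 1, sem_undefined=True)
    sem = float(np.std(exp_means, ddof=1) / math.sqrt(n))
    return EfficiencyResult(float(np.mean(exp_means)), sem, n)


def stability_curve(records: Sequence[PlateRecord]) -> list[float]:
    """Percent of initially picked lines viable at each round.

    Monotone non-increasing by construction (a dead line stays dead;
    violations in the input raise, naming the line).
    """
    if not records:
        raise ValueError("no plate records given")
    n_rounds = len(records[0].viable_by_round)
    for r in records:
        if len(r.viable_by_round) != n_rounds:
            raise ValueError(f"line {r.line_id}: inconsistent number of rounds")
    n = len(records)
    return [
        100.0 * sum(r.viable_by_round[i] for r in records) / n for i in range(n_rounds)
    ]


def gfp_fraction(records: Sequence[PlateRecord]) -> GfpResult:
    """Percent of final-round viable lines scored GFP-positive.

    Lines not viable at the final round are excluded from the
    denominator; viable lines without a GFP call are excluded and
    counted in ``n_unassessed``.  With no assessable viable line the
    percentage is not computable (None).
    """
    viable = [r for r in records if r.viable_final]
    assessed = [r for r in viable if r.gfp_positive is not None]
    n_pos = sum(r.gfp_positive for r in assessed)
    if not assessed:
        return GfpResult(None, len(viable), 0, len(viable))
    return GfpResult(
        100.0 * n_pos / len(assessed),
        len(viable),
        int(n_pos),
        len(viable) - len(assessed),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U_x = sum over pairs of [x > y] + 0.5 [x == y], via the rank-sum
    # identity with midranks for ties
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2)


def _exact_u_distribution(nx: int, ny: int) -> np.ndarray:
    """Counts of labelings by U value under H0 with no ties.

    Uses the standard recurrence f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u),
    f(0, n, 0) = f(m, 0, 0) = 1.
    """
    max_u = nx * ny
    # table[m][n] is an array over u of counts
    table: list[list[np.ndarray]] = [
        [None] * (ny + 1) for _ in range(nx + 1)  # type: ignore[list-item]
    ]
    for n in range(ny + 1):
        table[0][n] = np.array([1.0])
    for m in range(1, nx + 1):
        table[m][0] = np.array([1.0])
        for n in range(1, ny + 1):
            a = table[m - 1][n]
            b = table[m][n - 1]
            size = m * n + 1
            out = np.zeros(size)
            out[n : n + len(a)] += a
            out[: len(b)] += b
            table[m][n] = out
    return table[nx][ny]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
    alpha: float = 0.05,
    exact_cap: int = 2_000_000,
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    ``U`` is the statistic for ``x`` (number of (x, y) pairs with
    x > y, counting ties as 1/2).  The exact path enumerates the null
    distribution of U over all labelings (valid without ties); the
    approximate path uses the normal approximation with tie correction

        sigma_U^2 = nx*ny/12 * [(N+1) - sum(t^3 - t)/(N*(N-1))]

    and a 0.5 continuity correction.  ``auto`` picks exact when there
    are no ties and C(nx+ny, nx) <= ``exact_cap``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = xa.size, ya.size
    u_x = _u_statistic(xa, ya)
    combined = np.concatenate([xa, ya])
    has_ties = len(np.unique(combined)) < combined.size

    if mode == "auto":
        mode = (
            "exact"
            if not has_ties and math.comb(nx + ny, nx) <= exact_cap
            else "approx"
        )
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free samples")
        dist = _exact_u_distribution(nx, ny)
        total = dist.sum()
        u_lo = min(u_x, nx * ny - u_x)
        # two-tailed: both tails at least as extreme as the observed
        # deviation from the mean; symmetric null, so double the lower tail
        p = min(1.0, 2.0 * dist[: int(u_lo) + 1].sum() / total)
        method = "exact"
    elif mode == "approx":
        mu = nx * ny / 2.0
        N = nx + ny
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = nx * ny / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(0.0, abs(u_x - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * norm.sf(z))
        method = "normal_approx"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult("x", "y", u_x, float(p), method, alpha=alpha)


def compare_constructs(
    values: Mapping[str, Sequence[float]],
    baseline: str,
    alpha: float = 0.05,
    mode: Literal["auto", "exact", "approx"] = "auto",
    correction: Literal[None, "bonferroni", "bh"] = None,
) -> list[TestResult]:
    """Two-tailed Mann-Whitney tests of every construct against a baseline.

    ``values`` maps construct labels to per-experiment values (e.g.
    efficiencies).  Groups with fewer than 2 experiments are flagged and
    skipped.  No multiplicity adjustment is applied by default; pass
    ``correction`` for Bonferroni or Benjamini-Hochberg adjusted
    p-values (stored in ``p_adjusted``).
    """
    if baseline not in values:
        raise ValueError(f"baseline {baseline!r} not among constructs")
    base_vals = list(values[baseline])
    results: list[TestResult] = []
    for name, vals in values.items():
        if name == baseline:
            continue
        if len(vals) < 2 or len(base_vals) < 2:
            results.append(
                TestResult(name, baseline, math.nan, math.nan, "skipped", alpha, True)
            )
            continue
        res = mann_whitney_u(vals, base_vals, mode=mode, alpha=alpha)
        results.append(
            TestResult(name, baseline, res.U, res.p_two_tailed, res.method, alpha)
        )
    if correction is not None:
        _adjust(results, correction)
    return results


def _adjust(results: list[TestResult], method: str) -> None:
    from statsmodels.stats.multitest import multipletests

    tested = [r for r in results if not r.skipped]
    if not tested:
        return
    how = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    _, adj, _, _ = multipletests([r.p_two_tailed for r in tested], method=how)
    for r, p in zip(tested, adj):
        r.p_adjusted = float(p)


def summarize_screen(
    records: Sequence[PlateRecord],
    counts: Sequence[TransformationCount] = (),
) -> list[ScreenSummary]:
    """Per construct x strain: efficiency ± SEM, final-round viability %,
    GFP-positive % among viable lines."""
    rec_groups: dict[tuple[str, str], list[PlateRecord]] = {}
    for r in records:
        rec_groups.setdefault((r.construct, r.strain), []).append(r)
    count_groups: dict[tuple[str, str], list[TransformationCount]] = {}
    for c in counts:
        count_groups.setdefault((c.construct, c.strain), []).append(c)

    summaries = []
    for key in sorted(rec_groups):
        recs = rec_groups[key]
        curve = stability_curve(recs)
        gfp = gfp_fraction(recs)
        eff = (
            transformation_efficiency(count_groups[key]) if key in count_groups else None
        )
        n_exp = len({r.experiment_id for r in recs})
        summaries.append(
            ScreenSummary(
                construct=key[0],
                strain=key[1],
                efficiency_mean=eff.mean if eff else None,
                efficiency_sem=eff.sem if eff else None,
                pct_viable_final=curve[-1],
                pct_gfp_positive=gfp.pct_positive,
                n_lines=len(recs),
                n_experiments=n_exp,
            )
        )
    return summaries


def bubble_summary(summaries: Iterable[ScreenSummary]) -> pd.DataFrame:
    """Flat table of the three screen readouts per construct x strain,
    suitable for a stability-vs-GFP bubble plot sized by efficiency."""
    rows = [
        {
            "construct": s.construct,
            "strain": s.strain,
            "pct_viable_final": s.pct_viable_final,
            "pct_gfp_positive": s.pct_gfp_positive,
            "efficiency_mean": s.efficiency_mean,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "construct",
            "strain",
            "pct_viable_final",
            "pct_gfp_positive",
            "efficiency_mean",
        ],
    )


def records_from_frame(df: pd.DataFrame) -> list[PlateRecord]:
    """Build plate records from a table with columns line_id, construct,
    strain, selection, viable_r1..viable_rR, gfp, experiment_id."""
    round_cols = sorted(
        (c for c in df.columns if c.startswith("viable_r")),
        key=lambda c: int(c.removeprefix("viable_r")),
    )
    if not round_cols:
        raise ValueError("no viable_r<i> columns found")
    records = []
    for _, row in df.iterrows():
        gfp = row.get("gfp")
        gfp_val: bool | None
        if pd.isna(gfp) or gfp in ("", "NA", "not_assessed"):
            gfp_val = None
        else:
            gfp_val = bool(int(gfp))
        records.append(
            PlateRecord(
                line_id=str(row["line_id"]),
                construct=str(row["construct"]),
                strain=str(row["strain"]),
                selection=str(row.get("selection", "zeocin")),
                viable_by_round=tuple(bool(int(row[c])) for c in round_cols),
                gfp_positive=gfp_val,
                experiment_id=str(row.get("experiment_id", "E1")),
            )
        )
    return records


def counts_from_frame(df: pd.DataFrame) -> list[TransformationCount]:
    """Build colony counts from a table with columns construct, strain,
    experiment_id, colonies, dna_ug."""
    return [
        TransformationCount(
            construct=str(r["construct"]),
            strain=str(r["strain"]),
            experiment_id=str(r["experiment_id"]),
            colonies=int(r["colonies"]),
            dna_ug=float(r.get("dna_ug", 1.0)),
        )
        for _, r in df.iterrows()
    ]
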
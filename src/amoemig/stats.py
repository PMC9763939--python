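"""Replicate-aware migration statistics and transwell normalization.

Per-cell measurements from imaging experiments are not independent
samples: cells within one biological replicate share a batch.  The
SuperPlot convention therefore reduces each replicate to its median and
runs all hypothesis tests on replicate medians only, avoiding the
artificial inflation of n that pooling would cause.  This module
implements that reduction, one-way fixed-effects ANOVA, the
Tukey-Kramer post hoc test (valid for unequal replicate counts), and
the two transwell normalizations (percent of input, migration index).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SuperPlotSummary",
    "TranswellResult",
    "replicate_medians",
    "one_way_anova",
    "tukey_hsd",
    "transwell_percent_of_input",
    "migration_index",
    "superplot_summary",
    "grouped_values_from_long",
]

#: condition label -> replicate label -> per-cell scalar values
GroupedValues = Mapping[str, Mapping[str, Sequence[float]]]


class StatsValidationError(ValueError):
    pass


@dataclass
class SuperPlotSummary:
    """Replicate medians plus condition-level summary and tests."""

    medians: dict[str, dict[str, float]]  # condition -> replicate -> median
    condition_mean: dict[str, float]      # mean of replicate medians
    condition_sd: dict[str, float]        # sample SD (ddof=1) of medians
    n_replicates: dict[str, int]
    anova_F: float | None = None
    anova_p: float | None = None
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c,
                "n_replicates": self.n_replicates[c],
                "mean_of_medians": self.condition_mean[c],
                "sd_of_medians": self.condition_sd[c],
            }
            for c in self.medians
        ]
        return pd.DataFrame(rows)


@dataclass
class TranswellResult:
    """Normalized transwell counts per condition.

    ``migration_index`` is NaN for every condition when the reference
    condition had no transmigrated cells (fold change not computable).
    """

    percent_of_input: dict[str, float]
    migration_index: dict[str, float]
    reference: str
    mi_computable: bool = True


def _validate(gv: GroupedValues) -> None:
    if not gv:
        raise StatsValidationError("no conditions")
    for cond, reps in gv.items():
        if not reps:
            raise StatsValidationError(f"condition {cond!r} has no replicates")
        for rep, values in reps.items():
            if len(values) == 0:
                raise StatsValidationError(
                    f"empty replicate {rep!r} in condition {cond!r}"
                )


def replicate_medians(gv: GroupedValues) -> SuperPlotSummary:
    """Median per replicate; condition mean and SD over those medians.

    Cell-level values are never pooled across replicates: duplicating
    every cell measurement leaves all outputs unchanged.
    """
    _validate(gv)
    medians: dict[str, dict[str, float]] = {}
    cond_mean: dict[str, float] = {}
    cond_sd: dict[str, float] = {}
    n_rep: dict[str, int] = {}
    for cond, reps in gv.items():
        med = {rep: float(np.median(values)) for rep, values in reps.items()}
        medians[cond] = med
        vals = np.array(list(med.values()))
        cond_mean[cond] = float(vals.mean())
        cond_sd[cond] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        n_rep[cond] = len(vals)
    return SuperPlotSummary(medians, cond_mean, cond_sd, n_rep)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA on replicate medians.

    Returns (F, p).  F = MSB / MSW with the usual between/within sum-of-
    squares decomposition; p from the F(k-1, N-k) distribution.  When
    every group is constant and equal, F is 0 and p is 1.
    """
    if len(groups) < 2:
        raise StatsValidationError("ANOVA needs at least 2 conditions")
    arrs = {c: np.asarray(v, dtype=float) for c, v in groups.items()}
    for c, a in arrs.items():
        if len(a) < 2:
            raise StatsValidationError(
                f"condition {c!r} has {len(a)} value(s); ANOVA needs >= 2"
            )
    allv = np.concatenate(list(arrs.values()))
    grand = allv.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    dfb = len(arrs) - 1
    dfw = len(allv) - len(arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return float(F), p


def tukey_hsd(
    groups: Mapping[str, Sequence[float]]
) -> dict[tuple[str, str], float]:
    """Tukey-Kramer pairwise p-values on replicate medians.

    The studentized-range statistic for a pair (i, j) is
    ``q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` with MSW the
    within-group mean square from the one-way ANOVA; the Kramer form of
    the standard error makes the test valid for unequal replicate
    counts.  p-values come from the studentized range distribution with
    k groups and N - k error degrees of freedom, and are symmetric in
    the pair.
    """
    if len(groups) < 2:
        raise StatsValidationError("Tukey needs at least 2 conditions")
    arrs = {c: np.asarray(v, dtype=float) for c, v in groups.items()}
    for c, a in arrs.items():
        if len(a) < 2:
            raise StatsValidationError(
                f"condition {c!r} has {len(a)} value(s); Tukey needs >= 2"
            )
    k = len(arrs)
    N = sum(len(a) for a in arrs.values())
    dfw = N - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values()) / dfw
    out: dict[tuple[str, str], float] = {}
    for (ci, ai), (cj, aj) in itertools.combinations(arrs.items(), 2):
        diff = abs(ai.mean() - aj.mean())
        if msw == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / len(ai) + 1.0 / len(aj)))
            q = diff / se
            p = float(np.clip(sps.studentized_range.sf(q, k, dfw), 0.0, 1.0))
        out[(ci, cj)] = p
        out[(cj, ci)] = p
    return out


def superplot_summary(
    gv: GroupedValues, run_tests: bool | None = None
) -> SuperPlotSummary:
    """Full SuperPlot reduction: medians, ANOVA and Tukey where applicable.

    Tests run when every condition has >= 2 replicate medians and there
    are >= 2 conditions (Tukey also for exactly 2, giving the single
    comparison).
    """
    summary = replicate_medians(gv)
    groups = {c: list(m.values()) for c, m in summary.medians.items()}
    testable = len(groups) >= 2 and all(len(v) >= 2 for v in groups.values())
    if run_tests is None:
        run_tests = testable
    if run_tests:
        summary.anova_F, summary.anova_p = one_way_anova(groups)
        summary.tukey = tukey_hsd(groups)
    return summary


def grouped_values_from_long(df: pd.DataFrame) -> dict[str, dict[str, list[float]]]:
    """(condition, replicate, value) long table -> nested GroupedValues.

    NaN values (e.g. undefined confinement ratios) are dropped first.
    """
    for col in ("condition", "replicate", "value"):
        if col not in df.columns:
            raise StatsValidationError(f"missing column: {col}")
    df = df.dropna(subset=["value"])
    gv: dict[str, dict[str, list[float]]] = {}
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        gv.setdefault(str(cond), {})[str(rep)] = [float(v) for v in grp["value"]]
    return gv


def transwell_percent_of_input(migrated: float, input_count: float) -> float:
    """Transmigrated cells as a percentage of the loaded input."""
    if input_count <= 0:
        raise StatsValidationError("input count must be positive")
    if migrated < 0:
        raise StatsValidationError("negative migrated count")
    return 100.0 * migrated / input_count


def migration_index(
    counts: Mapping[str, float], reference: str
) -> TranswellResult:
    """Fold change in transmigration relative to an unstimulated reference.

    MI(c) = count(c) / count(reference), so the reference condition has
    MI = 1 exactly.  When the reference well had no transmigrated cells
    the fold change is undefined and every MI is flagged NaN rather
    than raised, mirroring how such assays are reported.
    """
    if reference not in counts:
        raise StatsValidationError(f"reference condition {reference!r} absent")
    ref = counts[reference]
    if ref <= 0:
        return TranswellResult(
            percent_of_input={},
            migration_index={c: float("nan") for c in counts},
            reference=reference,
            mi_computable=False,
        )
    mi = {c: float(v) / float(ref) for c, v in counts.items()}
    return TranswellResult(
        percent_of_input={}, migration_index=mi, reference=reference
    )
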
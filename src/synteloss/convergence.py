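"""Habitat-paired convergent gene-loss analysis.

The design pairs, within each phylum, one marine and one freshwater taxon.
A *freshwater lineage loss* is an orthogroup present in the marine member
and absent in the freshwater member (the marine direction is symmetric).
The analysis reports the k-of-n shared-loss counts (the full intersection
plus every leave-one-out intersection), a background shared-absence rate
over random taxon subsets of the same size, two-sample t-tests on the
leave-one-out vectors in all four standard variants (pooled/Welch x
one/two-sided), and an exact within-pair label-permutation test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io import OrthogroupMatrix

__all__ = [
    "HabitatPair",
    "HabitatPanel",
    "ConvergenceResult",
    "lineage_loss_set",
    "shared_loss_counts",
    "background_shared_absence",
    "habitat_t_test",
    "habitat_permutation_test",
    "convergence_analysis",
]

T_TEST_VARIANTS = (
    ("pooled", "two-sided"),
    ("pooled", "greater"),
    ("welch", "two-sided"),
    ("welch", "greater"),
)


@dataclass(frozen=True)
class HabitatPair:
    phylum: str
    marine: str
    freshwater: str


class HabitatPanel:
    """A list of habitat pairs, validated against an orthogroup matrix."""

    def __init__(self, pairs: Sequence[HabitatPair | tuple[str, str, str]]):
        self.pairs = [
            p if isinstance(p, HabitatPair) else HabitatPair(*p) for p in pairs
        ]
        taxa = [t for p in self.pairs for t in (p.marine, p.freshwater)]
        if len(set(taxa)) != len(taxa):
            raise ValueError("panel taxa must be distinct")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def taxa(self) -> list[str]:
        return [t for p in self.pairs for t in (p.marine, p.freshwater)]

    def validate(self, matrix: OrthogroupMatrix) -> None:
        missing = [t for t in self.taxa if t not in matrix.taxon_index]
        if missing:
            raise KeyError(f"panel taxa absent from matrix: {missing}")


def _loss_mask(
    matrix: OrthogroupMatrix,
    retained_taxon: str,
    lost_taxon: str,
    require_outside_presence: bool,
    outside_exclude: tuple[str, str],
) -> np.ndarray:
    for t in (retained_taxon, lost_taxon):
        if t not in matrix.taxon_index:
            raise KeyError(f"unknown taxon {t!r}")
    presence = matrix.presence()
    mask = presence[:, matrix.taxon_index[retained_taxon]] & ~presence[
        :, matrix.taxon_index[lost_taxon]
    ]
    if require_outside_presence:
        outside = [
            j for t, j in matrix.taxon_index.items() if t not in outside_exclude
        ]
        mask &= presence[:, outside].any(axis=1) if outside else False
    return mask


def lineage_loss_set(
    matrix: OrthogroupMatrix,
    pair: HabitatPair | tuple[str, str, str],
    direction: Literal["freshwater", "marine"] = "freshwater",
    require_outside_presence: bool = False,
) -> set[str]:
    """Orthogroups lost in one member of a habitat pair and retained in the other.

    ``direction="freshwater"``: present in the marine taxon, absent in the
    freshwater taxon (i.e. a freshwater-specific loss); ``"marine"`` is the
    mirror image.  With ``require_outside_presence`` the orthogroup must
    additionally be present in at least one taxon outside the pair.
    """
    if not isinstance(pair, HabitatPair):
        pair = HabitatPair(*pair)
    if direction == "freshwater":
        retained, lost = pair.marine, pair.freshwater
    elif direction == "marine":
        retained, lost = pair.freshwater, pair.marine
    else:
        raise ValueError(f"unknown direction {direction!r}")
    mask = _loss_mask(
        matrix, retained, lost, require_outside_presence, (pair.marine, pair.freshwater)
    )
    return {matrix.orthogroup_ids[i] for i in np.flatnonzero(mask)}


def shared_loss_counts(loss_sets: Sequence[set[str]]) -> tuple[int, list[int]]:
    """(|intersection of all n sets|, leave-one-out intersection sizes).

    ``leave_one_out[i]`` is the size of the intersection of every set except
    the i-th — the "lost in n-1 of n lineages including all others" count.
    """
    n = len(loss_sets)
    if n < 2:
        raise ValueError("need at least 2 loss sets")
    count_all = len(set.intersection(*map(set, loss_sets)))
    loo = [
        len(set.intersection(*(set(s) for j, s in enumerate(loss_sets) if j != i)))
        for i in range(n)
    ]
    return count_all, loo


def background_shared_absence(
    matrix: OrthogroupMatrix,
    subset_size: int,
    mode: Literal["exact", "montecarlo", "auto"] = "auto",
    n_draws: int = 1000,
    seed: int | None = None,
    exact_limit: int = 10_000,
) -> float:
    """Mean number of orthogroups absent in all of a random taxon subset.

    For each subset S of ``subset_size`` taxa, count orthogroups absent in
    every member of S and present in at least one taxon outside S; return
    the mean over subsets.  ``auto`` enumerates exactly when the number of
    subsets is at most ``exact_limit`` and otherwise Monte-Carlo samples
    ``n_draws`` subsets with the given seed.
    """
    n_taxa = len(matrix.taxa)
    if subset_size >= n_taxa:
        raise ValueError("subset_size must be smaller than the number of taxa")
    if subset_size < 1:
        raise ValueError("subset_size must be positive")
    presence = matrix.presence()
    present_anywhere = presence.any(axis=1)

    def count(cols: Sequence[int]) -> int:
        return int((~presence[:, list(cols)].any(axis=1) & present_anywhere).sum())

    if mode == "auto":
        mode = "exact" if comb(n_taxa, subset_size) <= exact_limit else "montecarlo"
    if mode == "exact":
        counts = [count(c) for c in itertools.combinations(range(n_taxa), subset_size)]
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        counts = [
            count(rng.choice(n_taxa, size=subset_size, replace=False))
            for _ in range(n_draws)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(counts))


@dataclass(frozen=True)
class TTestRecord:
    variant: str
    alternative: str
    t: float
    df: float
    p: float


def habitat_t_test(
    fw_counts: Sequence[float], marine_counts: Sequence[float]
) -> dict[tuple[str, str], TTestRecord]:
    """All four two-sample t-test variants on paired-lineage loss counts.

    Pooled-variance and Welch forms, each with a two-sided and a one-sided
    (freshwater > marine) p-value.  Nothing is silently chosen: callers get
    every variant.  Zero variance in both groups with equal means yields
    t = 0, p = 1 rather than an error.
    """
    a = np.asarray(fw_counts, dtype=float)
    b = np.asarray(marine_counts, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    out: dict[tuple[str, str], TTestRecord] = {}
    degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean()
    for variant, alternative in T_TEST_VARIANTS:
        if degenerate:
            df = 2 * len(a) - 2.0
            out[(variant, alternative)] = TTestRecord(variant, alternative, 0.0, df, 1.0)
            continue
        res = stats.ttest_ind(
            a, b, equal_var=(variant == "pooled"), alternative=alternative
        )
        out[(variant, alternative)] = TTestRecord(
            variant, alternative, float(res.statistic), float(res.df), float(res.pvalue)
        )
    return out


def _pack(mask: np.ndarray) -> np.ndarray:
    return np.packbits(mask.astype(np.uint8))


def _popcount(packed: np.ndarray) -> int:
    return int(np.bitwise_count(packed).sum())


def _and_reduce(rows: list[np.ndarray]) -> np.ndarray:
    out = rows[0].copy()
    for r in rows[1:]:
        out &= r
    return out


def _perm_statistic(
    fw_rows: list[np.ndarray], m_rows: list[np.ndarray], statistic: str
) -> float:
    n = len(fw_rows)
    if statistic == "all_n_diff":
        return float(_popcount(_and_reduce(fw_rows)) - _popcount(_and_reduce(m_rows)))
    if statistic == "loo_mean_diff":
        def loo_mean(rows: list[np.ndarray]) -> float:
            total = 0
            for i in range(n):
                total += _popcount(_and_reduce(rows[:i] + rows[i + 1:]))
            return total / n
        return loo_mean(fw_rows) - loo_mean(m_rows)
    raise ValueError(f"unknown statistic {statistic!r}")


def habitat_permutation_test(
    matrix: OrthogroupMatrix,
    panel: HabitatPanel,
    statistic: Literal["all_n_diff", "loo_mean_diff"] = "loo_mean_diff",
    exact: bool = True,
    seed: int | None = None,
    n_draws: int = 10_000,
    require_outside_presence: bool = False,
) -> float:
    """Within-pair label-swap permutation p-value for the habitat contrast.

    Marine/freshwater labels are swapped within pairs over all 2^n
    assignments (``exact``) or over ``n_draws`` sampled assignments; p is
    the proportion of assignments whose statistic is >= the observed one,
    counting the identity assignment.
    """
    panel.validate(matrix)
    n = len(panel)
    fw = [
        _pack(_loss_mask(matrix, p.marine, p.freshwater, require_outside_presence,
                         (p.marine, p.freshwater)))
        for p in panel
    ]
    mar = [
        _pack(_loss_mask(matrix, p.freshwater, p.marine, require_outside_presence,
                         (p.marine, p.freshwater)))
        for p in panel
    ]
    observed = _perm_statistic(fw, mar, statistic)

    def stat_for(signs) -> float:
        f = [fw[i] if s == 0 else mar[i] for i, s in enumerate(signs)]
        m = [mar[i] if s == 0 else fw[i] for i, s in enumerate(signs)]
        return _perm_statistic(f, m, statistic)

    if exact:
        values = [stat_for(s) for s in itertools.product((0, 1), repeat=n)]
        return sum(v >= observed for v in values) / len(values)
    rng = np.random.default_rng(seed)
    hits = 1  # the identity assignment
    for _ in range(n_draws):
        if stat_for(rng.integers(0, 2, size=n)) >= observed:
            hits += 1
    return hits / (n_draws + 1)


@dataclass
class ConvergenceResult:
    """Everything the habitat-paired loss analysis computes, JSON-serialisable."""

    panel: list[tuple[str, str, str]]
    require_outside_presence: bool
    fw_loss_sets: dict[str, list[str]]
    marine_loss_sets: dict[str, list[str]]
    fw_count_all: int
    fw_leave_one_out: list[int]
    marine_count_all: int
    marine_leave_one_out: list[int]
    background_mean: float
    background_mode: str
    t_tests: list[TTestRecord]
    permutation_p: float
    permutation_statistic: str
    nearest_variant_to_reference: str | None = None
    reference_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "panel": [list(p) for p in self.panel],
            "require_outside_presence": self.require_outside_presence,
            "fw_loss_sets": self.fw_loss_sets,
            "marine_loss_sets": self.marine_loss_sets,
            "fw_count_all": self.fw_count_all,
            "fw_leave_one_out": self.fw_leave_one_out,
            "marine_count_all": self.marine_count_all,
            "marine_leave_one_out": self.marine_leave_one_out,
            "background_mean": self.background_mean,
            "background_mode": self.background_mode,
            "t_tests": [
                {
                    "variant": r.variant,
                    "alternative": r.alternative,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                }
                for r in self.t_tests
            ],
            "permutation_p": self.permutation_p,
            "permutation_statistic": self.permutation_statistic,
        }
        if self.reference_p is not None:
            d["reference_p"] = self.reference_p
            d["nearest_variant_to_reference"] = self.nearest_variant_to_reference
        return d


def convergence_analysis(
    matrix: OrthogroupMatrix,
    panel: HabitatPanel,
    require_outside_presence: bool = False,
    background_subset_size: int | None = None,
    background_mode: Literal["exact", "montecarlo", "auto"] = "auto",
    seed: int | None = None,
    permutation_statistic: Literal["all_n_diff", "loo_mean_diff"] = "loo_mean_diff",
    reference_p: float | None = None,
) -> ConvergenceResult:
    """Run the full habitat-paired convergent-loss analysis on one panel."""
    panel.validate(matrix)
    fw_sets = {
        p.phylum: lineage_loss_set(matrix, p, "freshwater", require_outside_presence)
        for p in panel
    }
    m_sets = {
        p.phylum: lineage_loss_set(matrix, p, "marine", require_outside_presence)
        for p in panel
    }
    fw_all, fw_loo = shared_loss_counts([fw_sets[p.phylum] for p in panel])
    m_all, m_loo = shared_loss_counts([m_sets[p.phylum] for p in panel])
    subset_size = background_subset_size or len(panel)
    bg_mode = background_mode
    if bg_mode == "auto":
        bg_mode = (
            "exact"
            if comb(len(matrix.taxa), subset_size) <= 10_000
            else "montecarlo"
        )
    bg = background_shared_absence(
        matrix, subset_size, mode=bg_mode, seed=seed
    )
    t_tests = habitat_t_test(fw_loo, m_loo)
    perm_p = habitat_permutation_test(
        matrix, panel, statistic=permutation_statistic, exact=True,
        require_outside_presence=require_outside_presence,
    )
    nearest = None
    if reference_p is not None:
        nearest_key = min(t_tests, key=lambda k: abs(t_tests[k].p - reference_p))
        nearest = f"{nearest_key[0]}/{nearest_key[1]}"
    return ConvergenceResult(
        panel=[(p.phylum, p.marine, p.freshwater) for p in panel],
        require_outside_presence=require_outside_presence,
        fw_loss_sets={k: sorted(v) for k, v in fw_sets.items()},
        marine_loss_sets={k: sorted(v) for k, v in m_sets.items()},
        fw_count_all=fw_all,
        fw_leave_one_out=fw_loo,
        marine_count_all=m_all,
        marine_leave_one_out=m_loo,
        background_mean=bg,
        background_mode=bg_mode,
        t_tests=list(t_tests.values()),
        permutation_p=perm_p,
        permutation_statistic=permutation_statistic,
        nearest_variant_to_reference=nearest,
        reference_p=reference_p,
    )
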
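"""Double cross-validation split plans.

Outer layer: the cohort is partitioned into five near-equal test folds by
stratified rejection sampling — a candidate partition is accepted only when,
for every fold, the development set (the other ~80%) and the test fold show
no significant difference in diagnosis ratio, age, education, sex or APOE
allele count (Welch t-test for the continuous/mean variables, Fisher's exact
test for sex) at the configured alpha.

Inner layer: within each outer fold's development set, ten folds preserving
the early-AD : non-AD ratio (per-fold class counts within one of exact
proportionality), otherwise uniform at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UnsatisfiableConstraintsError

DEFAULT_BALANCE_VARS = ("diagnosis", "age", "education_years", "sex", "apoe_e4")


@dataclass
class SplitPlan:
    """Outer 5-fold test assignment plus per-outer-fold inner assignments."""

    outer: dict[str, int]                  # subject_id -> outer fold (1-based)
    inner: dict[int, dict[str, int]]       # outer fold -> {id -> inner fold}
    seed: int
    alpha: float
    n_outer: int
    n_inner: int
    constraint_report: dict[int, dict[str, float]] = field(default_factory=dict)

    def test_ids(self, outer_fold: int) -> list[str]:
        return sorted(i for i, f in self.outer.items() if f == outer_fold)

    def dev_ids(self, outer_fold: int) -> list[str]:
        return sorted(i for i, f in self.outer.items() if f != outer_fold)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "seed": self.seed, "alpha": self.alpha,
            "n_outer": self.n_outer, "n_inner": self.n_inner,
            "outer": self.outer,
            "inner": {str(k): v for k, v in self.inner.items()},
            "constraint_report": {
                str(k): v for k, v in self.constraint_report.items()},
        }, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SplitPlan":
        p = Path(str(text_or_path))
        raw = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(raw)
        return cls(
            outer=d["outer"],
            inner={int(k): v for k, v in d["inner"].items()},
            seed=d["seed"], alpha=d["alpha"],
            n_outer=d["n_outer"], n_inner=d["n_inner"],
            constraint_report={
                int(k): v for k, v in d["constraint_report"].items()},
        )


class FoldTriple(NamedTuple):
    outer_fold: int
    inner_fold: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


def _near_equal_sizes(n: int, k: int) -> list[int]:
    """Partition n into k near-equal parts, larger parts first."""
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _balance_pvalues(df: pd.DataFrame, in_test: np.ndarray,
                     balance_vars: Sequence[str]) -> dict[str, float]:
    dev, test = df.loc[~in_test], df.loc[in_test]
    out: dict[str, float] = {}
    for var in balance_vars:
        if var == "sex":
            table = [
                [(dev["sex"] == "F").sum(), (dev["sex"] != "F").sum()],
                [(test["sex"] == "F").sum(), (test["sex"] != "F").sum()],
            ]
            out[var] = float(stats.fisher_exact(table)[1])
        else:
            col = ("is_early_ad" if var == "diagnosis" else var)
            a = dev[col].to_numpy(float)
            b = test[col].to_numpy(float)
            out[var] = float(stats.ttest_ind(a, b, equal_var=False)[1])
    return out


def stratified_outer_split(cohort: pd.DataFrame,
                           n_outer: int = 5,
                           balance_vars: Sequence[str] = DEFAULT_BALANCE_VARS,
                           alpha: float = 0.05,
                           seed: int = 0,
                           max_attempts: int = 10_000) -> SplitPlan:
    """Draw outer test folds by rejection sampling under balance constraints.

    The candidate partition is class-stratified (early-AD counts per fold
    apportioned by largest remainder within near-equal fold sizes), then the
    whole plan is redrawn until every fold passes every balance test at
    ``alpha``.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cohort is empty")
    df = cohort.reset_index(drop=True).copy()
    df["is_early_ad"] = (df["group"] == "early_ad").astype(float)
    missing = [v for v in balance_vars
               if v not in ("diagnosis",) and v not in df.columns]
    if missing:
        raise ConfigurationError(f"balance variables missing: {missing}")

    rng = np.random.default_rng([seed, 31])
    n = len(df)
    sizes = np.array(_near_equal_sizes(n, n_outer))
    early_idx = df.index[df["is_early_ad"] == 1.0].to_numpy()
    other_idx = df.index[df["is_early_ad"] == 0.0].to_numpy()
    early_counts = _largest_remainder(len(early_idx), sizes.astype(float))
    other_counts = sizes - early_counts

    last_failure = "no attempt made"
    for _ in range(max_attempts):
        fold_of = np.empty(n, dtype=int)
        for idx, counts in ((early_idx, early_counts),
                            (other_idx, other_counts)):
            perm = rng.permutation(idx)
            start = 0
            for f in range(n_outer):
                fold_of[perm[start:start + counts[f]]] = f + 1
                start += counts[f]
        report: dict[int, dict[str, float]] = {}
        ok = True
        for f in range(1, n_outer + 1):
            pvals = _balance_pvalues(df, fold_of == f, balance_vars)
            report[f] = pvals
            bad = [v for v, p in pvals.items() if p < alpha]
            if bad:
                ok = False
                last_failure = f"fold {f}: {bad[0]} (p={pvals[bad[0]]:.4f})"
                break
        if ok:
            outer = {str(df.at[i, "subject_id"]): int(fold_of[i])
                     for i in range(n)}
            return SplitPlan(outer=outer, inner={}, seed=seed, alpha=alpha,
                             n_outer=n_outer, n_inner=0,
                             constraint_report=report)
    raise UnsatisfiableConstraintsError(
        f"no balanced split in {max_attempts} attempts; last failure: "
        f"{last_failure}")


def stratified_inner_folds(dev_subjects: pd.DataFrame,
                           n_inner: int = 10,
                           seed: int = 0) -> dict[str, int]:
    """Class-ratio-preserving inner folds over a development set."""
    df = dev_subjects.reset_index(drop=True)
    rng = np.random.default_rng([seed, 37])
    is_early = (df["group"] == "early_ad").to_numpy()
    if is_early.all() or (~is_early).all():
        raise ConfigurationError("development set must contain both classes")
    assignment: dict[str, int] = {}
    for mask in (is_early, ~is_early):
        idx = df.index[mask].to_numpy()
        counts = _largest_remainder(
            len(idx), np.ones(n_inner))  # near-equal within class
        # rotate so remainders do not always land on fold 1
        counts = np.roll(counts, int(rng.integers(n_inner)))
        perm = rng.permutation(idx)
        start = 0
        for f in range(n_inner):
            for i in perm[start:start + counts[f]]:
                assignment[str(df.at[i, "subject_id"])] = f + 1
            start += counts[f]
    return assignment


def make_split_plan(cohort: pd.DataFrame,
                    n_outer: int = 5,
                    n_inner: int = 10,
                    balance_vars: Sequence[str] = DEFAULT_BALANCE_VARS,
                    alpha: float = 0.05,
                    seed: int = 0,
                    max_attempts: int = 10_000) -> SplitPlan:
    """Full double cross-validation plan (outer + inner assignments)."""
    plan = stratified_outer_split(cohort, n_outer, balance_vars, alpha,
                                  seed, max_attempts)
    plan.n_inner = n_inner
    id_col = cohort.set_index("subject_id", drop=False)
    for f in range(1, n_outer + 1):
        dev = id_col.loc[plan.dev_ids(f)]
        plan.inner[f] = stratified_inner_folds(dev, n_inner,
                                               seed=seed * n_outer + f)
    return plan


def iterate_plan(plan: SplitPlan) -> Iterator[FoldTriple]:
    """Yield the n_outer * n_inner (train, val, test) triples."""
    for outer_fold in range(1, plan.n_outer + 1):
        test = plan.test_ids(outer_fold)
        inner = plan.inner[outer_fold]
        for inner_fold in range(1, plan.n_inner + 1):
            val = sorted(i for i, f in inner.items() if f == inner_fold)
            train = sorted(i for i, f in inner.items() if f != inner_fold)
            yield FoldTriple(outer_fold, inner_fold, train, val, test)
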
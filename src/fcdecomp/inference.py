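"""Within-subject permutation inference over effect magnitudes.

Participant-specific effect averages are compared with dependent-sample t
tests whose null distribution is generated by randomly swapping the two
effects' values within each participant (equivalently, sign-flipping the
paired differences).  The permutation p value uses the add-one convention
p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm) and is two-sided.  Families of
comparisons are corrected with Benjamini-Hochberg FDR.

Also provided: a two-way ANOVA reconstructed from printed cell summaries
(mean +/- SEM and n per cell), using unweighted-marginal-means (Type III)
contrasts, which lets published demographic tables be re-analysed without
raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PermTestResult:
    effect_a: str
    effect_b: str
    n: int
    t: float
    df: int
    sd_diff: float
    p: float
    cohens_d: float
    degenerate: bool = False
    fdr_significant: bool | None = None


@dataclass
class CellSummary:
    """One cell of a 2 x 2 between-subjects design (mean +/- SEM, n)."""

    a_level: str
    b_level: str
    n: int
    mean: float
    sem: float


def paired_permutation_ttest(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    effect_a: str = "a",
    effect_b: str = "b",
) -> PermTestResult:
    """Dependent-sample t test with a within-subject permutation null.

    Pairs with a missing value are dropped listwise.  t and Cohen's d are
    both computed from (a - b).  Zero-variance differences yield a
    degenerate result: t = 0 and p = 1 when all differences are zero, and
    no p value otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0):
            return PermTestResult(effect_a, effect_b, n, 0.0, n - 1, 0.0, 1.0, 0.0, True)
        t = float(np.sign(d.mean()) * np.inf)
        return PermTestResult(
            effect_a, effect_b, n, t, n - 1, 0.0, float("nan"), float("nan"), True
        )
    t_obs = d.mean() / (sd / np.sqrt(n))
    if rng is None:
        rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    flipped = signs * d
    t_star = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(n))
    p = (1 + int(np.sum(np.abs(t_star) >= np.abs(t_obs)))) / (1 + n_perm)
    return PermTestResult(
        effect_a=effect_a,
        effect_b=effect_b,
        n=n,
        t=float(t_obs),
        df=n - 1,
        sd_diff=float(sd),
        p=float(p),
        cohens_d=float(d.mean() / sd),
    )


def fdr_correct(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def default_comparisons(sample: str, mode: str = "pooled") -> list:
    """The study's comparison ladders.

    Controls-only: 4 comparisons (each effect vs its baseline and the other
    effects of the same type).  Two-group samples: 10 comparisons, with the
    group factor being diagnosis (patients and controls) or treatment
    response (patients only).  Per-task mode appends the three exploratory
    within-subject comparisons.
    """
    if sample == "controls":
        suite = [
            ("common", "session"),
            ("common", "sex"),
            ("session", "sex"),
            ("sex", "individual"),
        ]
    elif sample in ("all", "patients"):
        g = "diagnosis" if sample == "all" else "response"
        suite = [
            ("common", g),
            ("common", "session"),
            ("common", "sex"),
            (g, "session"),
            (g, "sex"),
            ("session", "sex"),
            (g, f"{g}_x_session"),
            ("sex", f"{g}_x_sex"),
            (f"{g}_x_session", f"{g}_x_sex"),
            (f"{g}_x_sex", "individual"),
        ]
    else:
        raise ValueError(f"unknown sample {sample!r}")
    if mode == "per-task":
        suite += [
            ("individual", "individual_x_session"),
            ("individual", "individual_x_task"),
            ("individual_x_session", "individual_x_task"),
        ]
    return suite


def run_comparison_suite(
    table: pd.DataFrame,
    comparisons: Sequence[tuple] | None = None,
    sample: str = "all",
    mode: str = "pooled",
    n_perm: int = 1000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Permutation t tests over a suite of effect pairs, FDR-corrected.

    ``table`` holds per-participant effect averages (subjects x effects).
    The FDR family is the whole suite of one sample x mode run.
    """
    if comparisons is None:
        comparisons = default_comparisons(sample, mode)
        present = set(table.columns)
        kept = [c for c in comparisons if set(c) <= present]
        if len(kept) < len(comparisons):
            # degenerate small samples can lack an effect entirely
            skipped = [c for c in comparisons if c not in kept]
            warnings.warn(f"skipping comparisons with absent effects: {skipped}")
        comparisons = kept
    missing = {e for pair in comparisons for e in pair} - set(table.columns)
    if missing:
        raise KeyError(f"effects not present in the magnitude table: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    results = [
        paired_permutation_ttest(
            table[ea].to_numpy(),
            table[eb].to_numpy(),
            n_perm=n_perm,
            rng=rng,
            effect_a=ea,
            effect_b=eb,
        )
        for ea, eb in comparisons
    ]
    ps = np.array([r.p for r in results])
    ok = np.isfinite(ps)
    flags = np.zeros(len(results), dtype=bool)
    if ok.any():
        flags[ok] = fdr_correct(ps[ok], q=q)
    for r, f in zip(results, flags):
        r.fdr_significant = bool(f)
    return pd.DataFrame(
        {
            "effect_a": [r.effect_a for r in results],
            "effect_b": [r.effect_b for r in results],
            "n": [r.n for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "sd_diff": [r.sd_diff for r in results],
            "p_perm": [r.p for r in results],
            "cohens_d": [r.cohens_d for r in results],
            "fdr_significant": [r.fdr_significant for r in results],
        }
    )


def anova_from_cell_summaries(cells: Sequence[CellSummary]) -> pd.DataFrame:
    """2 x 2 between-subjects ANOVA from printed cell means, SEMs and ns.

    Within-cell sums of squares are reconstructed from the SEMs
    (sd = sem * sqrt(n)); main effects and the interaction are tested with
    unweighted-marginal-means (Type III) contrasts on the cell means, which
    is exact for unbalanced designs when the summaries are unrounded.
    """
    if len(cells) != 4:
        raise ValueError("need exactly 4 cells of a 2 x 2 design")
    a_levels = sorted({c.a_level for c in cells})
    b_levels = sorted({c.b_level for c in cells})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("cells must span a 2 x 2 design")
    grid = {(c.a_level, c.b_level): c for c in cells}
    order = [(a, b) for a in a_levels for b in b_levels]
    n = np.array([grid[k].n for k in order], dtype=float)
    m = np.array([grid[k].mean for k in order], dtype=float)
    sem = np.array([grid[k].sem for k in order], dtype=float)
    if np.any(n < 2):
        raise ValueError("each cell needs n >= 2")
    if np.any(sem <= 0):
        raise ValueError("cell SEMs must be positive")
    sd = sem * np.sqrt(n)
    ss_within = float(np.sum((n - 1) * sd**2))
    df_error = int(n.sum() - 4)
    mse = ss_within / df_error
    contrasts = {
        "factor_a": np.array([0.5, 0.5, -0.5, -0.5]),
        "factor_b": np.array([0.5, -0.5, 0.5, -0.5]),
        "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
    }
    rows = []
    for name, c in contrasts.items():
        est = float(c @ m)
        ss = est**2 / float(np.sum(c**2 / n))
        F = ss / mse
        rows.append(
            {
                "effect": name,
                "F": F,
                "df1": 1,
                "df2": df_error,
                "p": float(stats.f.sf(F, 1, df_error)),
            }
        )
    return pd.DataFrame(rows)
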
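"""Balanced fully-within-subject factorial ANOVA, from first principles.

Implements the analysis chain used for cohort joint-angle tables: Type III
sums of squares for every main effect and interaction (identical to
sequential SS here because the design is balanced and fully crossed), each
effect tested against its own effect-by-subject interaction, Mauchly's
sphericity test on the orthonormal-contrast covariance of each effect,
Greenhouse-Geisser epsilon with df correction when sphericity is rejected,
simple main effects, and Bonferroni-adjusted pairwise comparisons.

The decomposition works on the complete ``subjects x levels...`` response
array by inclusion-exclusion over marginal means: for an index subset U
(subject axis included or not), the effect term at each cell of U is the
alternating sum of marginal means over subsets of U, and its sum of squares
is weighted by the number of observations per U-cell.  Summed over all
nonempty U this reproduces the corrected total SS exactly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

from .errors import (
    IncompleteDesignError,
    InsufficientDataError,
    MissingCellError,
)


# ---------------------------------------------------------------------------
# data marshalling

def _pivot(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Long table -> (n_subjects, k1, ..., km) response array.

    Levels are ordered by sorted unique value per factor.  Raises
    IncompleteDesignError unless every subject contributes exactly one
    observation to every factor-level combination.
    """
    levels = {f: sorted(data[f].unique()) for f in within}
    subjects = sorted(data[subject].unique())
    counts = data.groupby([subject] + list(within), observed=True)[dv].count()
    expected = len(subjects) * int(np.prod([len(levels[f]) for f in within]))
    if len(counts) != expected or (counts != 1).any():
        raise IncompleteDesignError(
            "design is not balanced: every subject must be observed exactly "
            "once at every factor-level combination"
        )
    idx = pd.MultiIndex.from_product(
        [subjects] + [levels[f] for f in within], names=[subject] + list(within))
    series = data.set_index([subject] + list(within))[dv].reindex(idx)
    shape = (len(subjects),) + tuple(len(levels[f]) for f in within)
    return series.to_numpy(float).reshape(shape), levels, subjects


def _subset_means(Y: np.ndarray):
    """Marginal mean (keepdims) for every subset of axes kept."""
    axes = tuple(range(Y.ndim))
    means = {}
    for r in range(len(axes) + 1):
        for keep in itertools.combinations(axes, r):
            drop = tuple(a for a in axes if a not in keep)
            means[keep] = Y.mean(axis=drop, keepdims=True) if drop else Y
    return means


def _effect_ss(Y: np.ndarray, means: dict, keep_axes: tuple) -> float:
    term = np.zeros_like(means[keep_axes])
    for r in range(len(keep_axes) + 1):
        for sub in itertools.combinations(keep_axes, r):
            sign = (-1) ** (len(keep_axes) - len(sub))
            term = term + sign * means[sub]
    reps = Y.size / term.size
    return float(reps * np.sum(term**2))


# ---------------------------------------------------------------------------
# degrees of freedom

def anova_dfs(factor_levels: list[int], n_subjects: int,
              names: list[str] | None = None) -> dict:
    """Uncorrected df per source and its error term.

    Main effect df = k-1; interaction df = product of (k_i - 1); the error
    df of any effect is effect df * (n_subjects - 1).
    """
    if n_subjects < 2 or any(k < 2 for k in factor_levels):
        raise IncompleteDesignError("need >= 2 subjects and >= 2 levels per factor")
    names = names or [chr(ord("A") + i) for i in range(len(factor_levels))]
    out = {}
    for r in range(1, len(factor_levels) + 1):
        for combo in itertools.combinations(range(len(factor_levels)), r):
            df_eff = int(np.prod([factor_levels[i] - 1 for i in combo]))
            source = ":".join(names[i] for i in combo)
            out[source] = {"df": df_eff, "df_error": df_eff * (n_subjects - 1)}
    return out


# ---------------------------------------------------------------------------
# sphericity

@dataclass(frozen=True)
class SphericityResult:
    """Mauchly's test and Greenhouse-Geisser epsilon for one effect."""

    effect: str
    mauchly_w: float
    chi_square: float
    df: int
    p_value: float
    epsilon_gg: float
    testable: bool
    note: str = ""


def _contrast_matrix(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrasts spanning the complement of the mean."""
    return null_space(np.ones((1, k))).T


def _effect_contrast(levels_per_factor: list[int], effect_axes: tuple) -> np.ndarray:
    """Kronecker contrast projecting cell vectors onto one within effect."""
    M = np.ones((1, 1))
    for j, k in enumerate(levels_per_factor):
        block = _contrast_matrix(k) if j in effect_axes else np.full((1, k), 1.0 / k)
        M = np.kron(M, block)
    return M


def _sphericity_from_scores(z: np.ndarray, effect: str,
                            n_variables: int | None = None) -> SphericityResult:
    """Mauchly W, chi-square p, and GG epsilon from per-subject contrast scores.

    ``n_variables`` is the width of the wide repeated-measures layout the
    contrasts were built from (all factor-level combinations); it only
    enters the second-order Box term of the chi-square approximation.
    """
    n, p = z.shape
    if n_variables is None:
        n_variables = p + 1
    if p == 1:
        return SphericityResult(effect, 1.0, float("nan"), 0, float("nan"),
                                1.0, False, "single contrast; sphericity vacuous")
    S = np.cov(z, rowvar=False, ddof=1)
    lam = np.linalg.eigvalsh(S)
    tr = float(lam.sum())
    if tr <= 0:
        return SphericityResult(effect, float("nan"), float("nan"),
                                p * (p + 1) // 2 - 1, float("nan"), 1.0,
                                False, "zero contrast variance")
    eps = tr**2 / (p * float(np.sum(lam**2)))
    eps = min(max(eps, 1.0 / p), 1.0)
    df = p * (p + 1) // 2 - 1
    if lam.min() <= 1e-12 * lam.max() or n - 1 < p:
        warnings.warn(
            f"effect {effect}: contrast covariance singular "
            f"(dim {p}, subjects {n}); Mauchly's test not available",
            stacklevel=2,
        )
        return SphericityResult(effect, 0.0, float("nan"), df, float("nan"),
                                eps, False, "singular contrast covariance")
    W = float(np.prod(lam / (tr / p)))
    # Box's chi-square approximation with second-order term, as in R's
    # mauchly.test: nd = error df, rho the Bartlett multiplier.
    nd = n - 1
    rho = 1.0 - (2 * p**2 + p + 2) / (6.0 * p * nd)
    chi2 = -rho * nd * math.log(max(W, 1e-300))
    w2 = ((p + 2) * (p - 1) * (p - 2) * (2 * p**3 + 6 * p**2 + 3 * n_variables + 2)
          / (288.0 * (nd * p * rho) ** 2))
    pr1 = float(stats.chi2.sf(chi2, df))
    pr2 = float(stats.chi2.sf(chi2, df + 4))
    pval = pr1 + w2 * (pr2 - pr1)
    return SphericityResult(effect, W, chi2, df, pval, eps, True)


def mauchly_test(data: pd.DataFrame, dv: str, within: list[str], subject: str,
                 effect: str | list[str] | None = None) -> SphericityResult:
    """Mauchly's sphericity test for one within effect.

    ``effect`` names the factor (or list of factors, for an interaction);
    defaults to the sole factor of a one-way design.
    """
    Y, levels, _ = _pivot(data, dv, within, subject)
    if effect is None:
        if len(within) != 1:
            raise ValueError("effect must be named for multi-factor designs")
        effect = within[0]
    factors = [effect] if isinstance(effect, str) else list(effect)
    axes = tuple(within.index(f) for f in factors)
    klist = [len(levels[f]) for f in within]
    M = _effect_contrast(klist, axes)
    z = Y.reshape(Y.shape[0], -1) @ M.T
    return _sphericity_from_scores(z, ":".join(factors),
                                   n_variables=int(np.prod(klist)))


# ---------------------------------------------------------------------------
# the ANOVA table

@dataclass
class AnovaResult:
    """Full within-subject ANOVA output.

    ``table`` rows carry the possibly GG-corrected df (and the matching
    mean square = SS/df); ``sphericity`` maps each effect to its
    :class:`SphericityResult`; ``subject_ss``/``ss_total`` complete the
    decomposition.
    """

    table: pd.DataFrame
    sphericity: dict
    subject_ss: float
    subject_df: int
    ss_total: float

    def to_markdown(self) -> str:
        lines = ["| Source | df | Type III SS | Mean square | F | P |",
                 "|---|---|---|---|---|---|"]
        for _, r in self.table.iterrows():
            df = f"{r['df']:.3f}" if r["correction"] != "none" else f"{int(round(r['df']))}"
            lines.append(
                f"| {r['source']} | {df} | {r['ss']:.3f} | {r['ms']:.3f} | "
                f"{r['F']:.3f} | {format_p(r['p_value'])} |"
            )
        return "\n".join(lines)


def format_p(p: float) -> str:
    """Render a p-value the way the summary tables print it."""
    if np.isnan(p):
        return "undefined"
    return "<0.0005" if p < 5e-4 else f"{p:.3f}"


def rm_anova(data: pd.DataFrame, dv: str, within: list[str], subject: str,
             correction: str = "auto", sphericity_alpha: float = 0.05) -> AnovaResult:
    """Repeated-measures factorial ANOVA on a balanced long table.

    Parameters
    ----------
    correction
        ``"auto"`` applies Greenhouse-Geisser to an effect when Mauchly's
        test rejects sphericity at ``sphericity_alpha`` (untestable
        effects, e.g. contrast dimension exceeding n-1, stay uncorrected);
        ``"gg"`` corrects every correctable effect; ``"none"`` never does.
    """
    if correction not in ("auto", "gg", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    Y, levels, subjects = _pivot(data, dv, within, subject)
    n = len(subjects)
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects")
    means = _subset_means(Y)
    ss_total = float(np.sum((Y - means[()]) ** 2))
    zero_variance = ss_total <= 1e-12 * max(float(np.sum(Y**2)), 1.0)

    klist = [len(levels[f]) for f in within]
    rows = []
    spher = {}
    m = len(within)
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            source = ":".join(within[i] for i in combo)
            keep = tuple(i + 1 for i in combo)  # +1: subject is axis 0
            ss = _effect_ss(Y, means, keep)
            ss_err = _effect_ss(Y, means, (0,) + keep)
            df_eff = int(np.prod([klist[i] - 1 for i in combo]))
            df_err = df_eff * (n - 1)

            M = _effect_contrast(klist, combo)
            z = Y.reshape(n, -1) @ M.T
            sp = _sphericity_from_scores(z, source,
                                         n_variables=int(np.prod(klist)))
            spher[source] = sp

            if correction == "none":
                apply_gg = False
            elif correction == "gg":
                apply_gg = sp.epsilon_gg < 1.0 and df_eff > 1
            else:
                apply_gg = (sp.testable and not np.isnan(sp.p_value)
                            and sp.p_value < sphericity_alpha)
            eps = sp.epsilon_gg if apply_gg else 1.0
            df_r, df_e = df_eff * eps, df_err * eps

            note = ""
            if zero_variance or ss_err <= 1e-12 * max(ss_total, 1.0):
                F = p = float("nan")
                note = "F undefined (zero error variance)"
            else:
                F = (ss / df_r) / (ss_err / df_e)
                p = float(stats.f.sf(F, df_r, df_e))
            rows.append(dict(
                source=source, df=df_r, ss=ss, ms=ss / df_r if df_r else np.nan,
                F=F, p_value=p,
                correction="greenhouse_geisser" if apply_gg else "none",
                epsilon=sp.epsilon_gg, error_ss=ss_err, error_df=df_e,
                note=note,
            ))
    subject_ss = _effect_ss(Y, means, (0,))
    return AnovaResult(table=pd.DataFrame(rows), sphericity=spher,
                       subject_ss=subject_ss, subject_df=n - 1,
                       ss_total=ss_total)


# ---------------------------------------------------------------------------
# follow-up tests

def simple_main_effects(data: pd.DataFrame, dv: str, target: str, subject: str,
                        by: list[str], fixed: dict | None = None,
                        correction: str = "auto") -> pd.DataFrame:
    """One-way RM ANOVA of ``target`` at each combination of ``by`` levels.

    Each combination uses its own within-combination error term (the
    target-by-subject interaction on the subset).  ``fixed`` restricts to a
    single named combination and raises :class:`MissingCellError` if it is
    absent from the data.
    """
    if fixed is not None:
        mask = np.ones(len(data), bool)
        for f, lv in fixed.items():
            mask &= (data[f] == lv).to_numpy()
        if not mask.any():
            raise MissingCellError(f"no records at {fixed}")
        combos = [tuple(fixed[f] for f in by)]
    else:
        combos = sorted(
            data[by].drop_duplicates().itertuples(index=False, name=None))
    rows = []
    for combo in combos:
        sub = data
        for f, lv in zip(by, combo):
            sub = sub[sub[f] == lv]
        res = rm_anova(sub, dv, [target], subject, correction=correction)
        row = res.table.iloc[0].to_dict()
        for f, lv in zip(by, combo):
            row[f] = lv
        rows.append(row)
    cols = list(by) + ["source", "df", "ss", "ms", "F", "p_value",
                       "correction", "epsilon", "error_ss", "error_df", "note"]
    return pd.DataFrame(rows)[cols]


def bonferroni_pairwise(data: pd.DataFrame, dv: str, target: str, subject: str,
                        by: list[str] | None = None, alpha: float = 0.05,
                        method: str = "paired",
                        family: str = "per_combination") -> pd.DataFrame:
    """Bonferroni-adjusted pairwise comparisons of ``target`` levels.

    Within each combination of ``by`` levels, every pair of target levels
    is compared on subject-paired values (collapsing any remaining factors
    by the subject mean).  ``method="paired"`` uses paired t-tests;
    ``method="pooled"`` uses the combination's one-way RM error term.  The
    Bonferroni family is the ``m = k(k-1)/2`` comparisons within one
    combination, or every comparison across combinations with
    ``family="global"``.  A direction string like ``"10 > 60"`` is emitted
    only when the adjusted p falls below ``alpha``.
    """
    if method not in ("paired", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    by = list(by or [])
    collapsed = (data.groupby([subject] + by + [target], observed=True)[dv]
                 .mean().reset_index())
    combos = (sorted(collapsed[by].drop_duplicates().itertuples(index=False, name=None))
              if by else [()])
    levels = sorted(collapsed[target].unique())
    pairs = list(itertools.combinations(levels, 2))
    m_per = len(pairs)
    m_global = m_per * len(combos)

    rows = []
    for combo in combos:
        sub = collapsed
        for f, lv in zip(by, combo):
            sub = sub[sub[f] == lv]
        wide = sub.pivot(index=subject, columns=target, values=dv)
        if wide.shape[0] < 2:
            raise InsufficientDataError("pairwise comparisons need >= 2 subjects")
        if method == "pooled":
            long = sub.rename(columns={dv: "y"})
            res = rm_anova(long, "y", [target], subject, correction="none")
            ms_err = res.table.iloc[0]["error_ss"] / res.table.iloc[0]["error_df"]
            df_err = res.table.iloc[0]["error_df"]
        for a, b in pairs:
            x, y = wide[a].to_numpy(), wide[b].to_numpy()
            diff = x - y
            n = len(diff)
            if method == "paired":
                sd = diff.std(ddof=1)
                t = diff.mean() / (sd / math.sqrt(n)) if sd > 0 else np.inf * np.sign(diff.mean() or 1)
                dof = n - 1
            else:
                t = diff.mean() / math.sqrt(2.0 * ms_err / n)
                dof = df_err
            p_raw = float(2 * stats.t.sf(abs(t), dof))
            m = m_global if family == "global" else m_per
            p_adj = min(1.0, m * p_raw)
            sig = p_adj < alpha
            direction = ""
            if sig:
                direction = f"{a} > {b}" if diff.mean() > 0 else f"{b} > {a}"
            row = dict(zip(by, combo))
            row.update(level_a=a, level_b=b, mean_diff=float(diff.mean()),
                       t=float(t), df=float(dof), p_raw=p_raw, m=m,
                       p_bonferroni=p_adj, significant=sig, direction=direction)
            rows.append(row)
    return pd.DataFrame(rows)
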
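"""Species-level trait handling: egg elongation and nest-type comparisons.

Egg elongation is the ratio of egg length to egg breadth (1.0 for a sphere
cross-section, larger for more elongate eggs).  Nest type is one of three
classes: ``cup`` (open top), ``dome`` (constructed roof) and ``cavity``
(burrow or hollow).  The species-level question is whether elongation
differs among nest types: one-way ANOVA with Tukey pairwise comparisons,
plus a family random-intercept mixed model as a shared-ancestry robustness
check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NEST_TYPES = ("cup", "dome", "cavity")

TRAIT_COLUMNS = [
    "species_id",
    "common_name",
    "family",
    "nest_type",
    "egg_length_mm",
    "egg_breadth_mm",
]


@dataclass
class NestTypeSummary:
    nest_type: str
    n: int
    mean_elongation: float
    se_elongation: float


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict


@dataclass
class TukeyResult:
    #: list of (group_a, group_b, mean_difference, adjusted_p)
    pairs: list


@dataclass
class RandomInterceptFit:
    fixed_effects: dict
    var_group: float
    var_resid: float
    log_reml: float
    wald_f: float
    wald_df: tuple


def compute_elongation(length, breadth, species_id=None):
    """Egg elongation L/B.  Raises on non-positive measurements."""
    length = np.asarray(length, dtype=float)
    breadth = np.asarray(breadth, dtype=float)
    bad = (length <= 0) | (breadth <= 0)
    if np.any(bad):
        if species_id is not None:
            offender = np.asarray(species_id)[np.atleast_1d(bad)][0]
            raise ValueError(f"non-positive egg measurement for species {offender!r}")
        raise ValueError("non-positive egg measurement")
    out = length / breadth
    return float(out) if out.ndim == 0 else out


def load_trait_table(source) -> pd.DataFrame:
    """Load and validate a species trait CSV (or DataFrame).

    Expected columns: species_id, common_name (optional), family, nest_type,
    egg_length_mm, egg_breadth_mm.  Rows lacking either egg measurement are
    dropped with a logged count.  Elongation is always recomputed from the
    measurements; a supplied ``elongation`` column is only cross-checked.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in ("species_id", "family", "nest_type",
                           "egg_length_mm", "egg_breadth_mm") if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if "common_name" not in df.columns:
        df["common_name"] = ""

    bad_type = ~df["nest_type"].isin(NEST_TYPES)
    if bad_type.any():
        raise ValueError(
            f"unknown nest_type values: {sorted(df.loc[bad_type, 'nest_type'].unique())}"
        )

    incomplete = df["egg_length_mm"].isna() | df["egg_breadth_mm"].isna()
    if incomplete.any():
        logger.info(
            "dropping %d species lacking egg measurements", int(incomplete.sum())
        )
        df = df.loc[~incomplete].copy()

    elong = compute_elongation(
        df["egg_length_mm"].to_numpy(),
        df["egg_breadth_mm"].to_numpy(),
        species_id=df["species_id"].to_numpy(),
    )
    if "elongation" in df.columns:
        rel = np.abs(df["elongation"].to_numpy() - elong) / elong
        n_off = int(np.nansum(rel > 1e-3))
        if n_off:
            logger.warning(
                "supplied elongation column disagrees with L/B for %d species", n_off
            )
    df["elongation"] = elong
    return df.reset_index(drop=True)


def screen_outliers(traits: pd.DataFrame, k_sd: float = 3.0):
    """Split species into (retained, flagged) by elongation distance from the mean.

    Flagged species have |elongation - mean| > k_sd * sd, with mean and the
    n-1 denominator sd taken over all species.
    """
    if len(traits) < 3:
        raise ValueError("outlier screening needs at least 3 species")
    e = traits["elongation"].to_numpy()
    mu = e.mean()
    sd = e.std(ddof=1)
    flagged_mask = np.abs(e - mu) > k_sd * sd
    return traits.loc[~flagged_mask].copy(), traits.loc[flagged_mask].copy()


def summarize_by_nest_type(traits: pd.DataFrame) -> list[NestTypeSummary]:
    """Per nest type: n, mean elongation, SE of the mean (sd/sqrt(n))."""
    out = []
    for nest in NEST_TYPES:
        grp = traits.loc[traits["nest_type"] == nest, "elongation"].to_numpy()
        if grp.size == 0:
            logger.warning("nest type %r has no species; omitted from summary", nest)
            continue
        if grp.size == 1:
            logger.warning("nest type %r has a single species; SE reported as 0", nest)
            se = 0.0
        else:
            se = grp.std(ddof=1) / np.sqrt(grp.size)
        out.append(NestTypeSummary(nest, int(grp.size), float(grp.mean()), float(se)))
    return out


def _as_groups(values_by_group) -> dict:
    if isinstance(values_by_group, dict):
        return {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    return {i: np.asarray(v, dtype=float) for i, v in enumerate(values_by_group)}


def anova_oneway(values_by_group) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within."""
    groups = _as_groups(values_by_group)
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.size for g in groups.values()])
    if np.any(ns < 1):
        raise ValueError("every group needs at least 1 value")
    n_total = int(ns.sum())
    if n_total <= k:
        raise ValueError("total N must exceed the number of groups")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    means = {g: float(v.mean()) for g, v in groups.items()}
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for v in groups.values()))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    if ss_between == 0.0 and ss_within == 0.0:
        raise ValueError("degenerate ANOVA: zero variance within and between groups")
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    f = np.inf if ms_w == 0.0 else (ss_between / df_b) / ms_w
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_b, df_w, p, means)


def tukey_hsd(values_by_group, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons with the Tukey-Kramer unequal-n adjustment.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group mean square and its residual degrees of freedom.
    """
    groups = _as_groups(values_by_group)
    k = len(groups)
    if k < 2:
        raise ValueError("Tukey needs at least 2 groups")
    ns = {g: v.size for g, v in groups.items()}
    n_total = sum(ns.values())
    df_w = n_total - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        raise ValueError("degenerate ANOVA: zero within-group variance")
    names = list(groups)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = float(groups[a].mean() - groups[b].mean())
            se = np.sqrt(ms_w / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
            pairs.append((a, b, diff, min(max(p_adj, 0.0), 1.0)))
    return TukeyResult(pairs)


def fit_random_intercept(
    traits: pd.DataFrame,
    response: str = "elongation",
    fixed: str = "nest_type",
    grouping: str = "family",
) -> RandomInterceptFit:
    """REML fit of response ~ fixed with a random intercept per grouping level.

    Used as a robustness check on the species-level ANOVA: taxonomic family
    absorbs shared-ancestry correlation.  Inference on the fixed factor is a
    plain Wald F with residual degrees of freedom.
    """
    import statsmodels.formula.api as smf

    if traits[grouping].nunique() < 2:
        raise ValueError("need at least 2 grouping levels")
    model = smf.mixedlm(
        f"{response} ~ C({fixed})", data=traits, groups=traits[grouping]
    )
    # gradient-based optimisers can fail when the group variance sits on the
    # zero boundary; fall back to derivative-free methods
    fit = None
    errors = []
    import warnings as _warnings
    for method in ("lbfgs", "powell", "nm"):
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                candidate = model.fit(reml=True, method=method, maxiter=2000)
            if np.isfinite(candidate.llf):
                fit = candidate
                break
            errors.append(f"{method}: non-finite REML criterion")
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"{method}: {exc}")
    if fit is None:
        raise RuntimeError(
            "mixed-model optimisation failed; criterion trace: " + "; ".join(errors)
        )

    fe_names = [n for n in fit.fe_params.index]
    fixed_effects = {n: float(fit.fe_params[n]) for n in fe_names}
    # Wald F for the fixed factor: joint test of all non-intercept terms
    idx = [i for i, n in enumerate(fe_names) if n != "Intercept"]
    beta = fit.fe_params.to_numpy()[idx]
    V = fit.cov_params().to_numpy()[np.ix_(idx, idx)]
    q = len(idx)
    wald_f = float(beta @ np.linalg.solve(V, beta) / q)
    df_den = len(traits) - len(fe_names)
    return RandomInterceptFit(
        fixed_effects=fixed_effects,
        var_group=float(np.asarray(fit.cov_re)[0, 0]),
        var_resid=float(fit.scale),
        log_reml=float(fit.llf),
        wald_f=wald_f,
        wald_df=(q, df_den),
    )


def summaries_to_frame(summaries: list[NestTypeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.nest_type, s.n, s.mean_elongation, s.se_elongation) for s in summaries],
        columns=["nest_type", "n", "mean_elongation", "se_elongation"],
    )


def tukey_to_frame(result: TukeyResult) -> pd.DataFrame:
    return pd.DataFrame(
        result.pairs, columns=["group_a", "group_b", "mean_difference", "adjusted_p"]
    )
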
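"""Protein-drug association with mixed-effect models over biological replicates.

Protein abundance is measured on several independent thaws of each cell
line; treating the thaws as biological replicates, the association between
a protein and a per-individual drug phenotype is estimated from

    protein ~ phenotype + (1 | individual)

fitted by maximum likelihood, with the phenotype p-value from a likelihood
ratio test of the fixed covariate.  Replicates with conflicting trends
attenuate significance relative to simply averaging the thaws, which is the
point of the design.  Also here: Storey q-values, growth-rate correlation
and adjustment, the nested variance decomposition used in pilot designs
(individual / thaw / culture), and the siRNA knockdown effect model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "VarianceDecomposition",
    "SirnaResult",
    "fit_mem_association",
    "fit_fixed_association",
    "assoc_scan",
    "storey_qvalues",
    "growth_correlation",
    "growth_adjusted_association",
    "variance_components",
    "sirna_effect",
]


@dataclass
class AssociationResult:
    antibody_id: str
    phenotype_id: str
    beta: float
    se: float
    p: float
    model: str  # "MEM" | "fixed"
    n_individuals: int
    n_replicates: int
    q: float = np.nan

    def as_row(self) -> dict:
        return {
            "antibody": self.antibody_id,
            "phenotype": self.phenotype_id,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "q": self.q,
            "model": self.model,
            "n_individuals": self.n_individuals,
            "n_replicates": self.n_replicates,
        }


@dataclass
class VarianceDecomposition:
    antibody_id: str
    fraction_individual: float
    fraction_thaw_within_individual: float
    fraction_residual: float
    fraction_culture_within_thaw: float = 0.0

    def __post_init__(self):
        total = (
            self.fraction_individual
            + self.fraction_thaw_within_individual
            + self.fraction_residual
            + self.fraction_culture_within_thaw
        )
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"variance fractions sum to {total}, not 1")


@dataclass
class SirnaResult:
    beta_log: float
    pct_change: float
    p: float
    shapiro_p: float
    model: str


# ---------------------------------------------------------------------------


def _prepare_protein(protein: pd.DataFrame, standardize: bool) -> pd.DataFrame:
    df = protein.dropna(subset=["value"]).copy()
    if standardize:
        sd = df["value"].std(ddof=1)
        if sd > 0:
            df["value"] = (df["value"] - df["value"].mean()) / sd
    return df


def _lrt_mixedlm(df: pd.DataFrame, covariates: list[str], tested: str) -> tuple[float, float, float]:
    """ML fit of value ~ covariates + (1|individual); LRT p for ``tested``."""
    import statsmodels.api as sm

    y = df["value"].to_numpy()
    X_full = sm.add_constant(df[covariates].to_numpy())
    reduced_cols = [c for c in covariates if c != tested]
    X_red = sm.add_constant(df[reduced_cols].to_numpy()) if reduced_cols else np.ones((len(df), 1))
    groups = df["individual"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, X_full, groups=groups).fit(reml=False)
        red = sm.MixedLM(y, X_red, groups=groups).fit(reml=False)
    j = 1 + covariates.index(tested)
    beta = float(full.fe_params[j])
    se = float(full.bse_fe[j])
    lr = max(0.0, 2.0 * (full.llf - red.llf))
    p = float(stats.chi2.sf(lr, df=1))
    return beta, se, max(p, np.nextafter(0, 1))


def fit_mem_association(
    protein: pd.DataFrame,
    phenotype: pd.Series,
    antibody_id: str = "antibody",
    phenotype_id: str = "phenotype",
    standardize: bool = True,
    extra_covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Mixed-effect association of one protein with one drug phenotype.

    ``protein``: tidy frame (individual, thaw, value), one row per
    biological replicate.  ``phenotype``: per-individual values, replicated
    across that individual's thaw rows (a per-thaw phenotype Series indexed
    by (individual, thaw) is also accepted).  Protein values are z-scored
    first so the coefficient is in protein SD units per phenotype unit.
    """
    df = _prepare_protein(protein, standardize)
    if isinstance(phenotype.index, pd.MultiIndex):
        df["pheno"] = [
            phenotype.get((i, t), np.nan) for i, t in zip(df["individual"], df["thaw"])
        ]
    else:
        df["pheno"] = df["individual"].map(phenotype)
    df = df.dropna(subset=["pheno"])
    n_ind = df["individual"].nunique()
    if n_ind < 10:
        raise ValueError("need >= 10 individuals")
    per_ind = df.groupby("individual")["thaw"].nunique()
    if (per_ind >= 2).sum() < 0.5 * n_ind:
        warnings.warn("fewer than half the individuals have >= 2 thaws")
    if df["pheno"].std(ddof=0) == 0:
        raise ValueError("degenerate covariate: phenotype has zero variance")

    if (per_ind == 1).all():
        warnings.warn("all individuals have a single replicate; falling back to OLS")
        return _ols_result(df, antibody_id, phenotype_id, model="fixed")

    # zero within-individual variance limit: MEM coincides with OLS on means
    within = df.groupby("individual")["value"].var(ddof=0)
    if within.max() < 1e-12:
        means = df.groupby("individual").agg(value=("value", "mean"), pheno=("pheno", "first"))
        res = _ols_on_means(means, antibody_id, phenotype_id)
        res.model = "MEM"
        res.n_replicates = len(df)
        return res

    beta, se, p = _lrt_mixedlm(df, ["pheno"], "pheno")
    return AssociationResult(
        antibody_id=antibody_id,
        phenotype_id=phenotype_id,
        beta=beta,
        se=se,
        p=p,
        model="MEM",
        n_individuals=n_ind,
        n_replicates=len(df),
    )


def _ols_on_means(means: pd.DataFrame, antibody_id, phenotype_id) -> AssociationResult:
    x = means["pheno"].to_numpy(dtype=float)
    y = means["value"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    return AssociationResult(
        antibody_id=antibody_id,
        phenotype_id=phenotype_id,
        beta=float(res.slope),
        se=float(res.stderr),
        p=float(max(res.pvalue, np.nextafter(0, 1))),
        model="fixed",
        n_individuals=len(means),
        n_replicates=len(means),
    )


def _ols_result(df: pd.DataFrame, antibody_id, phenotype_id, model: str) -> AssociationResult:
    means = df.groupby("individual").agg(value=("value", "mean"), pheno=("pheno", "first"))
    res = _ols_on_means(means, antibody_id, phenotype_id)
    res.model = model
    res.n_replicates = len(df)
    return res


def fit_fixed_association(
    protein: pd.DataFrame,
    phenotype: pd.Series,
    antibody_id: str = "antibody",
    phenotype_id: str = "phenotype",
    standardize: bool = True,
) -> AssociationResult:
    """Fixed-effect association: OLS of the per-individual mean protein."""
    df = _prepare_protein(protein, standardize)
    df["pheno"] = df["individual"].map(phenotype)
    df = df.dropna(subset=["pheno"])
    if df["pheno"].std(ddof=0) == 0:
        raise ValueError("degenerate covariate: phenotype has zero variance")
    return _ols_result(df, antibody_id, phenotype_id, model="fixed")


def assoc_scan(
    prot,
    phenotypes: pd.DataFrame,
    model: str = "MEM",
    standardize: bool = True,
    phenotype_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Associate every antibody with every phenotype column; add Storey q-values.

    ``prot`` is a ProteinMatrix; ``phenotypes`` a per-individual table.
    Returns the tidy association table (one row per antibody x phenotype),
    with q-values computed within each phenotype's set of tests.
    """
    long = prot.long()
    cols = phenotype_cols or [c for c in phenotypes.columns if c != "growth"]
    fit = fit_mem_association if model.upper() == "MEM" else fit_fixed_association
    rows = []
    for ph in cols:
        pheno = phenotypes[ph]
        for ab, grp in long.groupby("antibody", sort=False):
            res = fit(grp, pheno, antibody_id=ab, phenotype_id=ph, standardize=standardize)
            rows.append(res.as_row())
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for ph, grp in out.groupby("phenotype"):
        out.loc[grp.index, "q"] = storey_qvalues(grp["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# multiple testing


def storey_qvalues(p, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a lambda
    grid, smoothed with a least-squares cubic and read off at the largest
    lambda, then capped at 1.  For m < 100 tests the estimate is unstable
    and pi0 = 1 is used (reducing to Benjamini-Hochberg).  q_i is the usual
    step-up minimum of pi0 * m * p_(j) / j over j >= rank(p_i).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 100:
        pi0 = 1.0
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# growth


def growth_correlation(protein_means: pd.Series, growth: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of per-individual protein means with growth."""
    joined = pd.concat([protein_means.rename("prot"), growth.rename("growth")], axis=1).dropna()
    if len(joined) < 5:
        raise ValueError("need >= 5 paired observations")
    if joined["prot"].nunique() == 1 or joined["growth"].nunique() == 1:
        raise ValueError("constant input")
    rho, pval = stats.spearmanr(joined["prot"], joined["growth"])
    return float(rho), float(pval)


def growth_adjusted_association(
    protein: pd.DataFrame,
    phenotype: pd.Series,
    growth: pd.Series,
    antibody_id: str = "antibody",
    phenotype_id: str = "phenotype",
    standardize: bool = True,
) -> tuple[AssociationResult, AssociationResult | None]:
    """MEM association with and without growth rate as a fixed covariate.

    Returns (unadjusted, adjusted); adjusted is None (with a warning) when
    growth is collinear with the phenotype (|r| > 0.999).
    """
    n_ind = protein["individual"].nunique()
    have_growth = protein["individual"].map(growth).notna()
    if have_growth.mean() < 0.9:
        raise ValueError("growth rate available for < 90% of individuals")
    unadjusted = fit_mem_association(
        protein, phenotype, antibody_id, phenotype_id, standardize=standardize
    )
    common = phenotype.index.intersection(growth.index)
    g, ph = growth.loc[common], phenotype.loc[common]
    if g.std(ddof=0) == 0:
        raise ValueError("zero-variance growth rate")
    r = float(np.corrcoef(g, ph)[0, 1])
    if abs(r) > 0.999:
        warnings.warn("growth collinear with phenotype; adjusted fit skipped")
        return unadjusted, None

    df = _prepare_protein(protein, standardize)
    df["pheno"] = df["individual"].map(phenotype)
    df["growth"] = df["individual"].map(growth)
    df = df.dropna(subset=["pheno", "growth"])
    beta, se, p = _lrt_mixedlm(df, ["pheno", "growth"], "pheno")
    adjusted = AssociationResult(
        antibody_id=antibody_id,
        phenotype_id=phenotype_id + "_growth_adjusted",
        beta=beta,
        se=se,
        p=p,
        model="MEM",
        n_individuals=df["individual"].nunique(),
        n_replicates=len(df),
    )
    return unadjusted, adjusted


# ---------------------------------------------------------------------------
# variance components


def _pooled_var_of_means(means: pd.Series, parent_cols: list[str]) -> float:
    """Pooled within-parent variance of child means (unbiased, ddof per parent)."""
    if parent_cols:
        grp = means.groupby(level=parent_cols)
        ss = grp.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
        ddof = (grp.size() - 1).sum()
    else:
        ss = ((means - means.mean()) ** 2).sum()
        ddof = len(means) - 1
    if ddof <= 0:
        raise ValueError("not enough replication to decompose variance")
    return float(ss / ddof)


def variance_components(data: pd.DataFrame, antibody_id: str = "antibody") -> VarianceDecomposition:
    """Nested variance decomposition: individual / thaw / (culture) / residual.

    ``data`` needs columns individual, thaw, value, optionally culture.
    Components are estimated by nested-ANOVA method of moments (expected
    mean squares, truncated at zero) on the (near-)balanced designs this
    assay produces.  A level whose units carry single measurements is
    confounded with the level below it: with one measurement per
    (individual, thaw) — the production design — all within-individual
    variance is attributed to the thaw component, the design's unit of
    biological replication; singleton cultures contribute to the residual
    and the culture component reads zero.
    """
    df = data.dropna(subset=["value"]).copy()
    if df["individual"].nunique() < 2:
        raise ValueError("variance decomposition needs >= 2 individuals")
    has_culture = "culture" in df.columns and df["culture"].nunique() > 1

    levels = ["individual", "thaw"] + (["culture"] if has_culture else [])
    cell = df.groupby(levels)["value"]
    n_rep = float(cell.size().mean())
    replicated = cell.size().max() > 1
    if replicated:
        ss = cell.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
        ddof = (cell.size() - 1).sum()
        var_res = float(ss / ddof)
    else:
        var_res = 0.0
        n_rep = 1.0

    cell_means = cell.mean()
    if has_culture:
        n_cult = float(cell_means.groupby(level=["individual", "thaw"]).size().mean())
        v_cult = _pooled_var_of_means(cell_means, ["individual", "thaw"])
        if replicated:
            var_cult = max(0.0, v_cult - var_res / n_rep)
        else:
            # singleton cultures: sub-thaw variation is residual, culture 0
            var_cult, var_res = 0.0, v_cult
        thaw_means = cell_means.groupby(level=["individual", "thaw"]).mean()
        noise_thaw = (var_cult + var_res / n_rep) / n_cult if replicated else var_res / n_cult
    else:
        n_cult = 1.0
        var_cult = 0.0
        thaw_means = cell_means
        noise_thaw = var_res / n_rep

    n_thaw = float(thaw_means.groupby(level="individual").size().mean())
    v_thaw = _pooled_var_of_means(thaw_means, ["individual"])
    var_thaw = max(0.0, v_thaw - noise_thaw)
    if not has_culture and not replicated:
        # one measurement per thaw: thaw and residual are confounded;
        # attribute within-individual variance to the thaw level
        var_thaw, var_res = v_thaw, 0.0

    ind_means = thaw_means.groupby(level="individual").mean()
    v_ind = _pooled_var_of_means(ind_means, [])
    var_ind = max(0.0, v_ind - (var_thaw + noise_thaw) / n_thaw)
    total = var_ind + var_thaw + var_cult + var_res
    return VarianceDecomposition(
        antibody_id=antibody_id,
        fraction_individual=var_ind / total,
        fraction_thaw_within_individual=var_thaw / total,
        fraction_culture_within_thaw=var_cult / total,
        fraction_residual=var_res / total,
    )


# ---------------------------------------------------------------------------
# siRNA


def sirna_effect(responses: pd.DataFrame) -> SirnaResult:
    """Knockdown effect on log response with random line and experiment intercepts.

    ``responses``: rows (line, experiment, knockdown in {0,1}, response > 0).
    The fixed knockdown coefficient is on the log scale; ``pct_change`` is
    the implied multiplicative change exp(beta) - 1.  Degenerate groupings
    (single line and experiment) fall back to OLS with a warning.  Residual
    normality is reported via Shapiro-Wilk.
    """
    import statsmodels.api as sm

    df = responses.copy()
    if df["knockdown"].nunique() < 2:
        raise ValueError("need both knockdown and control rows")
    if (df["response"] <= 0).any():
        raise ValueError("responses must be positive for the log transform")
    df["logy"] = np.log(df["response"].astype(float))
    n_lines = df["line"].nunique()
    n_exps = df["experiment"].nunique()

    vc = {}
    if n_lines > 1:
        vc["line"] = "0 + C(line)"
    else:
        warnings.warn("single cell line: random line effect dropped")
    if n_exps > 1:
        vc["experiment"] = "0 + C(experiment)"
    else:
        warnings.warn("single experiment: random experiment effect dropped")

    if not vc:
        ols = sm.OLS(df["logy"], sm.add_constant(df["knockdown"].astype(float))).fit()
        beta = float(ols.params.iloc[1])
        p = float(ols.pvalues.iloc[1])
        resid = ols.resid
        model_name = "fixed"
    else:
        df["_one"] = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.MixedLM.from_formula(
                "logy ~ knockdown", groups="_one", re_formula="0", vc_formula=vc, data=df
            ).fit(reml=False)
            red = sm.MixedLM.from_formula(
                "logy ~ 1", groups="_one", re_formula="0", vc_formula=vc, data=df
            ).fit(reml=False)
        beta = float(full.fe_params["knockdown"])
        lr = max(0.0, 2.0 * (full.llf - red.llf))
        p = float(stats.chi2.sf(lr, df=1))
        resid = np.asarray(full.resid)
        model_name = "MEM"
    shapiro_p = float(stats.shapiro(resid).pvalue) if len(resid) >= 3 else np.nan
    return SirnaResult(
        beta_log=beta,
        pct_change=float(np.expm1(beta)),
        p=max(p, float(np.nextafter(0, 1))),
        shapiro_p=shapiro_p,
        model=model_name,
    )
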
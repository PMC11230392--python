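"""The behavioral statistics battery.

Mouse-level analyses of module expression and gross foraging measures:

* per-mouse module expression counts/frequencies and module diversity
  (distinct modules expressed ÷ total excursions);
* module-wise differential-expression tests between genotypes (exact
  Mann–Whitney rank-sum on per-mouse frequencies, Benjamini–Hochberg FDR
  within each sex × age × phase stratum, significance at q < 0.2);
* a linear model for the number of significant modules per stratum with a
  phase × age interaction;
* multiple regression of the six gross measures on age × genotype × sex ×
  phase with mouse-clustered errors and Holm post-hoc contrasts;
* the "second-guessing" memory response: per-minute Pot2 dwell during the
  Foraging phase, modelled with a mixed model (random intercept per mouse)
  testing the genotype × sex × age and genotype × age × time-bin
  interactions;
* PCA logistic regression predicting genotype from whole-behavior
  profiles, with likelihood-ratio and per-PC Wald tests and McFadden
  pseudo-R².

The analysis unit is always the mouse; excursion-level data are
aggregated per mouse before testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .geometry import ArenaGeometry

Q_SIGNIFICANT = 0.2          # module-wise FDR call threshold
GROSS_MEASURES = (
    "relative_time_in_center", "distance_traveled_cm", "number_of_excursions",
    "latency_to_enter_arena_s", "food_g", "sand_g",
)


@dataclass
class StatResult:
    """One test result in tidy form."""

    test: str
    stratum: str = ""
    term: str = ""
    estimate: float = np.nan
    statistic: float = np.nan
    df: float = np.nan
    p: float = np.nan
    q: float = np.nan
    n1: int = 0
    n2: int = 0
    note: str = ""


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def _finite_p(p: float, estimate: float, tol: float = 1e-10) -> float:
    """Degenerate fits (zero residual variance) give NaN p; a ~zero
    coefficient in a perfect fit carries no evidence, so p = 1."""
    if np.isfinite(p):
        return float(p)
    return 1.0 if abs(estimate) < tol else 0.0


# ---------------------------------------------------------------------------
# expression table and diversity
# ---------------------------------------------------------------------------


def expression_table(assignments: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse per-module expression counts and frequencies.

    ``assignments`` needs mouse_id, phase, module.  Returns long form:
    mouse_id, phase, module, count, total, freq plus the metadata strata.
    Mice with zero excursions in a phase simply have no rows (flagged
    upstream); an excursion whose mouse lacks metadata is an error.
    """
    unknown = set(assignments["mouse_id"]) - set(metadata["mouse_id"])
    if unknown:
        raise ValueError(f"excursions reference unknown mice: {sorted(unknown)}")
    counts = (assignments.groupby(["mouse_id", "phase", "module"])
              .size().rename("count").reset_index())
    totals = (assignments.groupby(["mouse_id", "phase"])
              .size().rename("total").reset_index())
    out = counts.merge(totals, on=["mouse_id", "phase"])
    out["freq"] = out["count"] / out["total"]
    return out.merge(metadata[["mouse_id", "genotype", "sex", "age"]], on="mouse_id")


def frequency_matrix(expression: pd.DataFrame, phase: str, modules=None) -> pd.DataFrame:
    """Mouse × module frequency pivot for one phase (absent modules → 0)."""
    sub = expression[expression["phase"] == phase]
    mat = sub.pivot_table(index="mouse_id", columns="module", values="freq",
                          fill_value=0.0, aggfunc="sum")
    if modules is not None:
        mat = mat.reindex(columns=modules, fill_value=0.0)
    return mat


def module_diversity(expression: pd.DataFrame) -> pd.DataFrame:
    """Distinct modules expressed ÷ total excursions, per mouse × phase."""
    div = (expression.groupby(["mouse_id", "phase"])
           .agg(n_modules=("module", "nunique"), total=("total", "first"))
           .reset_index())
    div["diversity"] = div["n_modules"] / div["total"]
    return div


def diversity_regression(diversity: pd.DataFrame, metadata: pd.DataFrame) -> list:
    """Per-sex linear model  diversity ~ age + genotype + age:genotype.

    Diversity is first averaged over phases within mouse (the mouse is the
    unit).  Returns coefficient t-tests as StatResult rows.
    """
    per_mouse = diversity.groupby("mouse_id")["diversity"].mean().reset_index()
    df = per_mouse.merge(metadata, on="mouse_id")
    out = []
    for sex, g in df.groupby("sex"):
        model = smf.ols("diversity ~ C(age) * C(genotype)", data=g).fit()
        for term in model.params.index:
            if term == "Intercept":
                continue
            out.append(StatResult(
                test="diversity_regression", stratum=f"sex={sex}", term=term,
                estimate=float(model.params[term]),
                statistic=float(model.tvalues[term]),
                df=float(model.df_resid), p=float(model.pvalues[term]),
                n1=int(len(g)),
            ))
    return out


# ---------------------------------------------------------------------------
# rank-sum testing with FDR
# ---------------------------------------------------------------------------


def mannwhitney_exact_p(x, y) -> tuple[float, float]:
    """Two-sided exact Mann–Whitney p by full enumeration (tie-aware).

    Returns (U of the first sample, p).  p is the permutation probability
    that U falls at least as far into either tail as observed:
    P(U <= U_min) + P(U >= n1*n2 - U_min), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = ss.rankdata(combined)
    r1 = ranks[:n1].sum()
    U1 = r1 - n1 * (n1 + 1) / 2.0
    u_min = min(U1, n1 * n2 - U1)
    lo = hi = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if u <= u_min + 1e-9:
            lo += 1
        if u >= n1 * n2 - u_min - 1e-9:
            hi += 1
    p = min(1.0, (lo + hi) / total)
    return float(U1), p


def ranksum_test(x, y, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Two-sided rank-sum test: exact enumeration for small samples,
    tie-corrected normal approximation otherwise.  Returns (U, p, method)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2.0), 1.0, "degenerate"
    if min(len(x), len(y)) <= exact_max_n:
        U, p = mannwhitney_exact_p(x, y)
        return U, p, "exact"
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_module_expression(expression: pd.DataFrame, sex: str, age: str,
                           phase: str, modules=None) -> list:
    """Module-wise genotype tests within one sex × age × phase stratum.

    Rank-sum on per-mouse module frequencies (KO vs WT), BH-adjusted across
    the modules tested in the stratum; significance is q < 0.2.
    """
    sub = expression[(expression["sex"] == sex) & (expression["age"] == age)
                     & (expression["phase"] == phase)]
    meta = sub[["mouse_id", "genotype"]].drop_duplicates()
    groups = {g: m["mouse_id"].tolist() for g, m in meta.groupby("genotype")}
    for geno in ("KO", "WT"):
        if not groups.get(geno):
            raise ValueError(
                f"genotype {geno} absent in stratum sex={sex}, age={age}, phase={phase}")
    if modules is None:
        modules = sorted(expression["module"].unique())
    mat = frequency_matrix(sub, phase, modules)
    mat = mat.reindex(meta["mouse_id"], fill_value=0.0)
    ko = mat.loc[groups["KO"]]
    wt = mat.loc[groups["WT"]]
    stratum = f"sex={sex},age={age},phase={phase}"
    results = []
    for mod in modules:
        xv, yv = ko[mod].to_numpy(), wt[mod].to_numpy()
        if np.all(xv == 0) and np.all(yv == 0):
            U, p, method = float(len(xv) * len(yv) / 2), 1.0, "allzero"
        else:
            U, p, method = ranksum_test(xv, yv)
        results.append(StatResult(
            test="module_expression", stratum=stratum, term=f"module={mod}",
            estimate=float(xv.mean() - yv.mean()), statistic=U, p=p,
            n1=len(xv), n2=len(yv), note=method))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def count_significant(results, q_threshold: float = Q_SIGNIFICANT) -> int:
    return int(sum(r.q < q_threshold for r in results))


def significant_count_model(counts: pd.DataFrame) -> StatResult:
    """Linear model for per-stratum significant-module counts.

    ``counts`` has one row per sex × age × phase cell with column
    ``n_significant``; the model is n ~ phase * age + sex and the reported
    result is the phase:age interaction t-test.
    """
    for col in ("sex", "age", "phase", "n_significant"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col}")
    for col in ("sex", "age", "phase"):
        if counts[col].nunique() < 2:
            raise ValueError(f"factor {col} needs at least 2 levels")
    model = smf.ols("n_significant ~ C(phase) * C(age) + C(sex)", data=counts).fit()
    term = [t for t in model.params.index if ":" in t][0]
    est = float(model.params[term])
    if model.mse_resid < 1e-12:  # perfect fit: a ~zero term carries no signal
        est = 0.0 if abs(est) < 1e-8 else est
        return StatResult(test="significant_count_model", term=term,
                          estimate=est, statistic=np.nan, df=float(model.df_resid),
                          p=1.0 if est == 0.0 else 0.0, n1=int(len(counts)))
    return StatResult(
        test="significant_count_model", term=term,
        estimate=est, statistic=float(model.tvalues[term]),
        df=float(model.df_resid), p=_finite_p(model.pvalues[term], est),
        n1=int(len(counts)))


# ---------------------------------------------------------------------------
# gross-measure regressions
# ---------------------------------------------------------------------------


def gross_measure_regression(gross: pd.DataFrame, metadata: pd.DataFrame,
                             alpha: float = 0.05) -> list:
    """Multiple regression per gross measure with Holm post-hoc contrasts.

    For each of the six measures: OLS of value on age × genotype × sex ×
    phase (all interactions) with cluster-robust (by mouse) covariance for
    the repeated phase factor.  Within measures showing a significant
    genotype-involving term, per-cell (sex × age × phase) Welch contrasts
    KO vs WT are reported with Holm adjustment.
    """
    df = gross.merge(metadata.drop(columns=[c for c in ("food_g", "sand_g")
                                            if c in metadata.columns
                                            and c in gross.columns]),
                     on="mouse_id")
    missing = [m for m in GROSS_MEASURES if m not in df.columns]
    if missing:
        raise ValueError(f"gross table missing measures: {missing}")
    out = []
    for measure in GROSS_MEASURES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.ols(
                f"{measure} ~ C(age) * C(genotype) * C(sex) * C(phase)", data=df,
            ).fit(cov_type="cluster", cov_kwds={"groups": df["mouse_id"]})
        geno_sig = False
        for term in model.params.index:
            if term == "Intercept":
                continue
            p = _finite_p(model.pvalues[term], float(model.params[term]))
            out.append(StatResult(
                test="gross_regression", stratum=f"measure={measure}", term=term,
                estimate=float(model.params[term]),
                statistic=float(model.tvalues[term]), p=p, n1=int(len(df))))
            if "genotype" in term and p < alpha:
                geno_sig = True
        if geno_sig:
            posthoc = []
            for (sex, age, phase), cell in df.groupby(["sex", "age", "phase"]):
                ko = cell.loc[cell["genotype"] == "KO", measure]
                wt = cell.loc[cell["genotype"] == "WT", measure]
                if len(ko) < 2 or len(wt) < 2:
                    continue
                tstat, p = ss.ttest_ind(ko, wt, equal_var=False)
                posthoc.append(StatResult(
                    test="gross_posthoc", stratum=f"measure={measure}",
                    term=f"sex={sex},age={age},phase={phase}",
                    estimate=float(ko.mean() - wt.mean()),
                    statistic=float(tstat), p=float(p),
                    n1=len(ko), n2=len(wt), note="holm"))
            if posthoc:
                adj = multipletests([r.p for r in posthoc], method="holm")[1]
                for r, q in zip(posthoc, adj):
                    r.q = float(q)
                out.extend(posthoc)
    return out


# ---------------------------------------------------------------------------
# second-guessing (Pot2 revisits in the Foraging phase)
# ---------------------------------------------------------------------------


def secondguess_series(annotated: pd.DataFrame, geometry: ArenaGeometry,
                       n_bins: int = 30) -> pd.DataFrame:
    """Per-minute Pot2 dwell during the Foraging phase, per mouse.

    Bin b (1-based) covers [60(b−1), 60b) seconds.  Returns long form
    (mouse_id, bin, dwell_s, cum_dwell_s); bins with no samples are 0.
    """
    phases = set(annotated["phase"].unique())
    if "Foraging" not in phases:
        raise ValueError("second-guessing is defined on the Foraging phase; "
                         f"got phases {sorted(phases)}")
    sub = annotated[annotated["phase"] == "Foraging"]
    rows = []
    for mid, g in sub.groupby("mouse_id"):
        t = g["t_s"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        at_pot2 = (g["zone"] == "Pot2").to_numpy()
        bins = np.minimum((t // 60).astype(int), n_bins - 1)
        dwell = np.bincount(bins[at_pot2], minlength=n_bins)[:n_bins] * dt
        dwell = np.minimum(dwell, 60.0)
        cum = np.cumsum(dwell)
        for b in range(n_bins):
            rows.append((mid, b + 1, float(dwell[b]), float(cum[b])))
    return pd.DataFrame(rows, columns=["mouse_id", "bin", "dwell_s", "cum_dwell_s"])


def secondguess_model(series: pd.DataFrame, metadata: pd.DataFrame) -> list:
    """Mixed model for per-bin Pot2 dwell with random intercept per mouse.

    dwell ~ genotype*sex*age + genotype*age*bin (bin numeric, centred).
    Reports Wald z tests, in particular the genotype:sex:age and
    genotype:age:bin three-way interactions.  A singular fit falls back to
    OLS with mouse-clustered errors (noted in the result).
    """
    df = series.merge(metadata[["mouse_id", "genotype", "sex", "age"]], on="mouse_id")
    df = df.copy()
    df["bin_c"] = df["bin"] - df["bin"].mean()
    formula = ("dwell_s ~ C(genotype) * C(sex) * C(age) "
               "+ C(genotype) * C(age) * bin_c")
    note = "mixedlm"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=df["mouse_id"]).fit(reml=True)
            if not np.all(np.isfinite(fit.bse[fit.params.index[:-1]])):
                raise np.linalg.LinAlgError("singular covariance")
            params, bses, pvals = fit.params, fit.bse, fit.pvalues
        except (np.linalg.LinAlgError, ValueError):
            note = "ols_cluster_fallback"
            fit = smf.ols(formula, df).fit(cov_type="cluster",
                                           cov_kwds={"groups": df["mouse_id"]})
            params, bses, pvals = fit.params, fit.bse, fit.pvalues
    out = []
    n_mice = df["mouse_id"].nunique()
    for term in params.index:
        if term in ("Intercept", "Group Var"):
            continue
        out.append(StatResult(
            test="secondguess_model", term=term, estimate=float(params[term]),
            statistic=float(params[term] / bses[term]) if bses[term] > 0 else np.nan,
            p=float(pvals[term]), n1=int(n_mice), note=note))
    return out


def secondguess_interaction_p(results, which: str) -> float:
    """Extract the three-way interaction p: which ∈ {'geno_sex_age', 'geno_age_bin'}."""
    for r in results:
        parts = r.term
        if which == "geno_sex_age" and all(k in parts for k in
                                           ("genotype", "sex", "age")) and "bin" not in parts:
            return r.p
        if which == "geno_age_bin" and all(k in parts for k in
                                           ("genotype", "age", "bin_c")) and "sex" not in parts:
            return r.p
    raise KeyError(which)


def group_bin_curves(series: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM dwell per genotype × sex × age × bin (for plotting)."""
    df = series.merge(metadata[["mouse_id", "genotype", "sex", "age"]], on="mouse_id")
    g = df.groupby(["genotype", "sex", "age", "bin"])["dwell_s"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "dwell_mean_s", "sem": "dwell_sem_s",
                               "count": "n"})


# ---------------------------------------------------------------------------
# PCA logistic genotype prediction
# ---------------------------------------------------------------------------


@dataclass
class PCALogitResult:
    n_pcs: int
    lr_statistic: float
    lr_p: float
    pc_p: dict                      # PC name -> Wald p
    mcfadden_r2: float
    loadings: np.ndarray = field(repr=False, default=None)
    note: str = ""
    variance_metric: str = "mcfadden_pseudo_r2"


def pca_logit_predict(profiles: pd.DataFrame, genotypes: pd.Series,
                      var_target: float = 0.90, max_pcs: int = 10) -> PCALogitResult:
    """Predict genotype from per-mouse behavior profiles via PCA + logistic.

    Columns are z-scored (constants dropped), PCs retained up to
    ``var_target`` cumulative variance (capped at ``max_pcs``), and a
    logistic regression of genotype (KO = 1) on the retained PCs is
    tested against the intercept-only model by likelihood ratio.
    The retained count is additionally capped at n/10 (one parameter per
    ten mice): with the small per-stratum samples of this assay the
    asymptotic likelihood-ratio test is badly anti-conservative at ten
    retained PCs, and the events-per-parameter cap restores calibration.
    Perfect separation triggers a ridge-stabilised refit (noted).
    """
    from sklearn.decomposition import PCA

    y = (genotypes.to_numpy() == "KO").astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both genotypes must be present")
    X = profiles.astype(float)
    sd = X.std(axis=0, ddof=0)
    X = (X.loc[:, sd > 1e-12] - X.loc[:, sd > 1e-12].mean()) / sd[sd > 1e-12]
    n, p = X.shape
    pca = PCA(n_components=min(p, n - 1, max(1, n - 2)), svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_target) + 1)
    k = max(1, min(k, max_pcs, max(1, n // 10), scores.shape[1]))
    if n < k + 2:
        raise ValueError(f"stratum too small: n={n} for {k} retained PCs")
    Z = sm.add_constant(scores[:, :k])
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Z).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)) or np.abs(fit.params).max() > 50:
                raise RuntimeError("separation suspected")
            llf = float(fit.llf)
            pvals = fit.pvalues[1:]
        except Exception:
            note = "ridge_stabilised"
            glm = sm.GLM(y, Z, family=sm.families.Binomial())
            fit = glm.fit_regularized(alpha=0.05, L1_wt=0.0)
            eta = Z @ fit.params
            mu = 1 / (1 + np.exp(-eta))
            mu = np.clip(mu, 1e-9, 1 - 1e-9)
            llf = float((y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum())
            pvals = np.full(k, np.nan)
    pbar = y.mean()
    llnull = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    lr = max(0.0, 2 * (llf - llnull))
    lr_p = float(ss.chi2.sf(lr, df=k))
    r2 = max(0.0, 1 - llf / llnull) if llnull < 0 else 0.0
    return PCALogitResult(
        n_pcs=k, lr_statistic=lr, lr_p=lr_p,
        pc_p={f"PC{i + 1}": float(pv) for i, pv in enumerate(np.atleast_1d(pvals))},
        mcfadden_r2=float(r2), loadings=pca.components_[:k], note=note)
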
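"""Statistical experiments on genotype-network scans.

Four analyses mirror the study design:

* **subsampling curves** — how the per-window property means respond to the
  number of haplotypes sampled per population (and pooled globally), with
  replicate means and standard errors;
* **property correlations** — pairwise Pearson coefficients between the
  network properties and the window covariables (physical span,
  recombination distance);
* **annotation-class ANCOVA** — ordinary linear model of each property on
  the window annotation class with the recombination distance as a
  covariable, high-recombination windows removed, pairwise class contrasts
  Bonferroni-corrected;
* **scenario comparison** — two-sided rank-sum tests of per-window property
  distributions between a neutral and a sweep scan, with shift directions
  and quantile-quantile pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from dataclasses import replace as dataclass_replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_scan import GLOBAL, scan
from .haplotype_io import HaplotypeMatrix
from .network_core import PROPERTY_NAMES
from .simulator import SimulationConfig, simulate_neutral, simulate_sweep

__all__ = [
    "subsampling_experiment",
    "correlate_properties",
    "ancova_annotation",
    "compare_scenarios",
    "scenario_replicates",
    "ScenarioComparison",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZES = (5000, 4000, 3000, 2000, 1000, 500, 300, 100)


def subsampling_experiment(
    matrix: HaplotypeMatrix,
    k: int = 11,
    sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES,
    replicates: int = 5,
    seed: int | None = None,
    include_global: bool = True,
) -> pd.DataFrame:
    """Mean +/- SEM of per-window property means versus sample size.

    For each size and population (plus the pooled GLOBAL sample of the same
    size), haplotypes are drawn without replacement, the window scan is run
    at window size ``k`` on the full matrix's sites, properties are averaged
    over windows, and the replicate mean and standard error of that average
    are reported.  Plotting conventions elsewhere may scale the SEM (the
    study's figures use 6x SEM error bars); the raw SEM is returned.
    """
    pops = matrix.populations()
    for size in sizes:
        for pop in pops:
            if size > len(matrix.rows_for_population(pop)):
                raise ValueError(
                    f"sample size {size} exceeds the haplotype count of {pop}"
                )
    ss = np.random.SeedSequence(seed)
    groups: list[tuple[str, np.ndarray]] = [
        (p, matrix.rows_for_population(p)) for p in pops
    ]
    if include_global and len(pops) > 1:
        groups.append((GLOBAL, np.arange(matrix.n_haplotypes)))
    records = []
    for (label, rows), child in zip(groups, ss.spawn(len(groups))):
        rng = np.random.default_rng(child)
        # one permutation per replicate; truncation nests the sizes within
        # a replicate, making n_vertices monotone per replicate, not only
        # in expectation
        perms = [rng.permutation(rows) for _ in range(replicates)]
        for size in sizes:
            per_rep = []
            for perm in perms:
                sub = matrix.subset_rows(np.sort(perm[:size]))
                sub.population_labels = np.full(sub.n_haplotypes, label, dtype=object)
                res = scan(sub, k=k, include_global=False)
                per_rep.append(res[list(PROPERTY_NAMES)].mean(numeric_only=True))
            reps = pd.concat(per_rep, axis=1).T
            for prop in PROPERTY_NAMES:
                records.append(
                    {
                        "population": label,
                        "sample_size": size,
                        "property": prop,
                        "mean": reps[prop].mean(),
                        "sem": reps[prop].sem() if replicates > 1 else np.nan,
                        "replicates": replicates,
                    }
                )
    return pd.DataFrame(records)


def correlate_properties(
    result: pd.DataFrame,
    covariables: tuple[str, ...] = ("span_bp", "recomb_cM"),
    population: str | None = None,
    log_vertices: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between window properties and
    covariables.

    Returns (coefficients, p-values) square DataFrames.  Rows with an
    undefined value are dropped pairwise; a constant column yields NaN, not
    an error.  ``log_vertices`` correlates log10(n_vertices) instead (the
    size-degree relation strengthens on a log scale).
    """
    if population is None:
        pops = result["population"].unique()
        population = GLOBAL if GLOBAL in pops else pops[0]
    sub = result[result["population"] == population]
    columns = [c for c in covariables if sub[c].notna().any()] + list(PROPERTY_NAMES)
    data = sub[columns].astype(float).copy()
    if len(data) < 3:
        raise ValueError("at least 3 windows are required for correlations")
    if log_vertices:
        data["n_vertices"] = np.log10(data["n_vertices"])
    names = list(data.columns)
    coef = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            pair = data[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(pair[a], pair[b])
            coef.loc[a, b] = coef.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return coef, pval


def ancova_annotation(
    result: pd.DataFrame,
    recomb_cutoff_cM: float = 1.0,
    population: str | None = None,
    interaction: bool = False,
) -> dict[str, pd.DataFrame]:
    """Annotation-class comparison of window properties, adjusted for
    recombination.

    Windows with more than ``recomb_cutoff_cM`` between their first and last
    SNV, and windows of class ``no_annotation``, are excluded.  For each
    property an ordinary linear model ``property ~ C(class) + recomb_cM``
    (optionally with interaction) is fitted; the class F-test, all pairwise
    class contrasts with Bonferroni correction, and covariable-adjusted
    class means (+/- 2 SEM, the figure convention) are returned as the
    DataFrames ``group_tests``, ``contrasts`` and ``adjusted_means``.
    """
    import statsmodels.formula.api as smf

    if population is None:
        pops = result["population"].unique()
        population = GLOBAL if GLOBAL in pops else pops[0]
    sub = result[
        (result["population"] == population)
        & (result["annotation_class"] != "no_annotation")
        & (result["recomb_cM"].notna())
        & (result["recomb_cM"] <= recomb_cutoff_cM)
    ].copy()
    if sub.empty:
        raise ValueError(
            "no windows left after the recombination cutoff and class filters"
        )
    classes = sorted(sub["annotation_class"].unique())
    small = {c for c in classes if (sub["annotation_class"] == c).sum() < 2}
    if small:
        logger.warning("classes with <2 windows skipped in contrasts: %s", sorted(small))
    group_rows, contrast_rows, mean_rows = [], [], []
    n_contrasts = max(
        1, len([c for c in classes if c not in small]) * (len(classes) - len(small) - 1) // 2
    )
    for prop in PROPERTY_NAMES:
        data = sub[["annotation_class", "recomb_cM", prop]].dropna().rename(
            columns={prop: "y"}
        )
        if data["annotation_class"].nunique() < 2:
            continue
        formula = (
            "y ~ C(annotation_class) * recomb_cM"
            if interaction
            else "y ~ C(annotation_class) + recomb_cM"
        )
        fit = smf.ols(formula, data=data).fit()
        from statsmodels.stats.anova import anova_lm

        anova = anova_lm(fit, typ=2)
        group_rows.append(
            {
                "property": prop,
                "F": anova.loc["C(annotation_class)", "F"],
                "p_value": anova.loc["C(annotation_class)", "PR(>F)"],
                "n_windows": len(data),
            }
        )
        # covariable-adjusted means at the mean recombination distance
        mean_cm = data["recomb_cM"].mean()
        for cls in classes:
            if cls in small:
                continue
            pred = fit.get_prediction(
                pd.DataFrame({"annotation_class": [cls], "recomb_cM": [mean_cm]})
            )
            mean_rows.append(
                {
                    "property": prop,
                    "annotation_class": cls,
                    "adjusted_mean": float(pred.predicted_mean[0]),
                    "sem": float(pred.se_mean[0]),
                    "lower_2sem": float(pred.predicted_mean[0] - 2 * pred.se_mean[0]),
                    "upper_2sem": float(pred.predicted_mean[0] + 2 * pred.se_mean[0]),
                }
            )
        usable = [c for c in classes if c not in small]
        for i, a in enumerate(usable):
            for b in usable[i + 1 :]:
                # effect of class b relative to class a, holding recomb fixed
                contrast = _class_contrast(fit, a, b, classes)
                raw_p = float(contrast.pvalue)
                contrast_rows.append(
                    {
                        "property": prop,
                        "class_a": a,
                        "class_b": b,
                        "effect": float(np.squeeze(contrast.effect)),
                        "p_raw": raw_p,
                        "p_bonferroni": min(1.0, n_contrasts * raw_p),
                    }
                )
    return {
        "group_tests": pd.DataFrame(group_rows),
        "contrasts": pd.DataFrame(contrast_rows),
        "adjusted_means": pd.DataFrame(mean_rows),
    }


def _class_contrast(fit, a: str, b: str, classes: list[str]):
    """t-test of the b-minus-a class effect from the fitted model."""
    names = list(fit.params.index)
    vec = np.zeros(len(names))
    for cls, sign in ((b, 1.0), (a, -1.0)):
        term = f"C(annotation_class)[T.{cls}]"
        if term in names:  # the reference class has no term
            vec[names.index(term)] += sign
    return fit.t_test(vec)


@dataclass
class ScenarioComparison:
    """Rank-sum comparison of two scans, per property."""

    table: pd.DataFrame  # property, statistic, p_value, direction, medians
    qq_pairs: dict[str, pd.DataFrame]  # property -> (quantile, neutral, sweep)


def compare_scenarios(
    neutral_scan: pd.DataFrame,
    sweep_scan: pd.DataFrame,
    population: str = GLOBAL,
    n_qq: int = 101,
) -> ScenarioComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test per property over
    window values, with the direction of the median shift (sweep minus
    neutral) and quantile-quantile pairs.

    Ties are handled by midranks with the normal approximation and
    continuity correction; the exact distribution is used when both groups
    are smaller than 25.
    """
    rows = []
    qq: dict[str, pd.DataFrame] = {}
    for scan_df in (neutral_scan, sweep_scan):
        if scan_df.empty:
            raise ValueError("cannot compare empty scans")
    a_all = neutral_scan[neutral_scan["population"] == population]
    b_all = sweep_scan[sweep_scan["population"] == population]
    if a_all.empty or b_all.empty:
        raise ValueError(f"population {population!r} missing from a scan")
    probs = np.linspace(0, 1, n_qq)
    for prop in PROPERTY_NAMES:
        a = a_all[prop].dropna().to_numpy(dtype=float)
        b = b_all[prop].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        method = "exact" if max(len(a), len(b)) < 25 and not (
            len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        ) else "asymptotic"
        res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method)
        med_diff = float(np.median(b) - np.median(a))
        direction = int(np.sign(med_diff)) if med_diff else int(
            np.sign(np.mean(b) - np.mean(a))
        )
        rows.append(
            {
                "property": prop,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "direction": direction,
                "median_neutral": float(np.median(a)),
                "median_sweep": float(np.median(b)),
            }
        )
        qq[prop] = pd.DataFrame(
            {
                "quantile": probs,
                "neutral": np.quantile(a, probs),
                "sweep": np.quantile(b, probs),
            }
        )
    return ScenarioComparison(table=pd.DataFrame(rows), qq_pairs=qq)


def scenario_replicates(
    config: SimulationConfig,
    n_pairs: int,
    k: int = 11,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired neutral/sweep replicate simulations scanned into pooled
    per-window properties.

    Each pair shares a replicate index; both arms use the collapsed
    panmictic configuration (the sweep model's requirement) so that the only
    difference between arms is the sweep itself.  Returns the long-form
    table of window property values with ``scenario`` in {neutral, sweep}
    and ``replicate`` columns; feed per-scenario slices to
    :func:`compare_scenarios` or aggregate per replicate for paired tests.
    """
    if config.sweep is None:
        raise ValueError("config must carry sweep parameters")
    base_seed = seed if seed is not None else config.seed
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_pairs)
    out = []
    for r in range(n_pairs):
        neutral_cfg = dataclass_replace(
            config,
            sweep=None,
            collapse_populations=True,
            seed=int(seeds[2 * r]) % (2**31 - 1),
        )
        sweep_cfg = dataclass_replace(
            config,
            collapse_populations=True,
            seed=int(seeds[2 * r + 1]) % (2**31 - 1),
        )
        for scenario, cfg in (("neutral", neutral_cfg), ("sweep", sweep_cfg)):
            matrix = (
                simulate_neutral(cfg) if scenario == "neutral" else simulate_sweep(cfg)
            )
            pooled = matrix
            pooled.population_labels = np.full(
                pooled.n_haplotypes, GLOBAL, dtype=object
            )
            res = scan(pooled, k=k, include_global=False)
            res["scenario"] = scenario
            res["replicate"] = r
            out.append(res)
    return pd.concat(out, ignore_index=True)
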
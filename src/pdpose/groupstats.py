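"""Longitudinal distribution statistics, task scores and treatment response.

Distribution drift is quantified as the Kullback-Leibler divergence between
Gaussian-KDE estimates of a feature at baseline and at later weeks, over
repeated 150-clip subsamples. Behavioural task scores (beam walking BWS,
rotarod RRS, tail-suspension TSS) follow their published best-two-trial /
clasping-class formulas. Treatment response evaluation (TRE) categorises
each feature from three Welch's t-tests (disease vs control, treated vs
control, treated vs disease), Holm-Sidak corrected across the feature
family, into unaffected / completely treated / partially treated /
treat-associated / untreated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DensityEstimate",
    "TaskScore",
    "kde",
    "kl_divergence",
    "longitudinal_divergence",
    "normalise",
    "group_difference",
    "score_task",
    "score_tss",
    "classify_affected",
    "classify_tre",
    "TreatmentResponseModel",
    "TreatmentLedgerResults",
    "TRE_CATEGORIES",
]

DENSITY_FLOOR = 1e-12
BWS_EXCLUSION = 600.0  # percent of baseline; failure type II
TRE_CATEGORIES = ("unaffected", "completely_treated", "partially_treated",
                  "treat_associated", "untreated")


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int


def kde(values: np.ndarray, grid: np.ndarray | None = None,
        n_grid: int = 200) -> DensityEstimate:
    """Gaussian kernel density estimate with Scott's bandwidth.

    The default grid spans the sample range extended by three bandwidths,
    200 points. Raises on degenerate (zero-variance) samples.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 5:
        raise ValueError("need at least 5 values for a KDE")
    if values.std() == 0:
        raise ValueError("degenerate sample: zero variance")
    k = stats.gaussian_kde(values)  # Scott's rule by default
    bw = float(k.factor * values.std(ddof=1))
    if grid is None:
        grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    density = k(grid)
    return DensityEstimate(grid=np.asarray(grid, float), density=density,
                           bandwidth=bw, n=values.size)


def kl_divergence(p: DensityEstimate, q: DensityEstimate) -> float:
    """KL divergence D(p||q) on p's grid.

    q is interpolated onto p's grid; the integral of p ln(p/q) is taken by
    the trapezoidal rule restricted to grid points where both densities
    exceed the 1e-12 floor. Raises when the supports do not overlap.
    """
    qd = np.interp(p.grid, q.grid, q.density, left=0.0, right=0.0)
    mask = (p.density > DENSITY_FLOOR) & (qd > DENSITY_FLOOR)
    if mask.sum() < 2:
        raise ValueError("density supports do not overlap")
    x = p.grid[mask]
    integrand = p.density[mask] * np.log(p.density[mask] / qd[mask])
    return float(np.trapezoid(integrand, x))


def longitudinal_divergence(values_by_week: dict[int, np.ndarray],
                            n_sets: int = 6, set_size: int = 150,
                            seed: int = 0, baseline_week: int = 0) -> pd.DataFrame:
    """Per-week KL divergence from the baseline distribution.

    For each of ``n_sets`` seeded subsamples of ``set_size`` clips per week
    (without replacement; with replacement when a week has fewer clips),
    compute D(baseline KDE || week KDE) on the baseline grid. Returns a
    tidy frame (week, set, kl).
    """
    if baseline_week not in values_by_week:
        raise ValueError("baseline week missing")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sets):
        samples = {}
        for week, vals in values_by_week.items():
            vals = np.asarray(vals, float)
            vals = vals[np.isfinite(vals)]
            replace = len(vals) < set_size
            samples[week] = rng.choice(vals, set_size, replace=replace)
        base = kde(samples[baseline_week])
        for week in sorted(values_by_week):
            qw = kde(samples[week], grid=base.grid)
            rows.append({"week": week, "set": s,
                         "kl": kl_divergence(base, qw)})
    return pd.DataFrame(rows)


def normalise(values: np.ndarray, log: bool = False) -> np.ndarray:
    """Min-max normalisation to [0, 1]; optional ln(x + 1e-6) first.

    A constant input maps to all zeros.
    """
    x = np.asarray(values, float)
    if log:
        x = np.log(x + 1e-6)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def group_difference(mean_exp: float, sem_exp: float,
                     mean_ndc: float, sem_ndc: float) -> tuple[float, float]:
    """Mean difference (exp - control) with error-propagated SEM."""
    if sem_exp < 0 or sem_ndc < 0:
        raise ValueError("SEMs must be >= 0")
    return mean_exp - mean_ndc, float(np.hypot(sem_exp, sem_ndc))


@dataclass
class TaskScore:
    mouse_id: str
    kind: str            # BWS / RRS / TSS
    value: float
    excluded: bool = False
    reason: str = ""


def score_task(baseline: np.ndarray, test: np.ndarray, mode: str,
               mouse_id: str = "m0") -> TaskScore:
    """Best-two-trials task score as percent of baseline.

    BWT keeps the two shortest traverse latencies, RRT the two longest
    latencies to fall. A BWS above 600% is flagged excluded (failure
    type II).
    """
    baseline = np.sort(np.asarray(baseline, float))
    test = np.sort(np.asarray(test, float))
    if baseline.size < 2 or test.size < 2:
        raise ValueError("need at least 2 trials per session")
    if mode == "BWT":
        b, t, kind = baseline[:2], test[:2], "BWS"
    elif mode == "RRT":
        b, t, kind = baseline[-2:], test[-2:], "RRS"
    else:
        raise ValueError(f"unknown task mode {mode!r}")
    score = 100.0 * t.mean() / b.mean()
    excluded = kind == "BWS" and score > BWS_EXCLUSION
    return TaskScore(mouse_id=mouse_id, kind=kind, value=float(score),
                     excluded=excluded,
                     reason="failure type II (BWS > 600%)" if excluded else "")


def score_tss(incidence_durations: dict[int, list[float]],
              mouse_id: str = "m0") -> TaskScore:
    """Tail-suspension clasping score.

    ``incidence_durations`` maps clasping class (1, 2, 3) to the durations
    (s) of observed incidences. A class scores 1 iff it has >= 2 incidences
    each longer than 2 s; TSS = c1 + 2*c2 + 3*c3.
    """
    total = 0
    for klass in (1, 2, 3):
        durs = [d for d in incidence_durations.get(klass, []) if d > 2.0]
        total += klass * (1 if len(durs) >= 2 else 0)
    return TaskScore(mouse_id=mouse_id, kind="TSS", value=float(total))


def _welch_corrected(a: np.ndarray, b: np.ndarray, alpha: float):
    """Per-feature Welch t-tests (columns) with Holm-Sidak correction.

    Returns (significant, raw_p, corrected_p); zero-variance-both features
    get p = 1 (not significant).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, float)
    p = np.where(np.isnan(p), 1.0, p)
    with np.errstate(divide="ignore"):  # p == 1 exactly (e.g. zero variance)
        sig, p_corr, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return sig, p, p_corr


def classify_affected(ct: np.ndarray, pd_vals: np.ndarray,
                      feature_names=None, alpha: float = 0.05) -> pd.DataFrame:
    """Label features affected/unaffected by disease.

    Columns of ``ct``/``pd_vals`` are features, rows animals. Affected iff
    the Holm-Sidak-corrected Welch p-value < alpha.
    """
    ct = np.atleast_2d(np.asarray(ct, float))
    pd_vals = np.atleast_2d(np.asarray(pd_vals, float))
    if ct.shape[0] < 3 or pd_vals.shape[0] < 3:
        raise ValueError("need at least 3 values per group")
    sig, p, p_corr = _welch_corrected(ct, pd_vals, alpha)
    names = feature_names if feature_names is not None \
        else [f"f{i}" for i in range(ct.shape[1])]
    return pd.DataFrame({"feature": names, "p": p, "p_corrected": p_corr,
                         "affected": sig})


def classify_tre(ct: np.ndarray, disease: np.ndarray, treated: np.ndarray,
                 feature_names=None, alpha: float = 0.05) -> pd.DataFrame:
    """Treatment-response category per feature.

    With S(x,y) the Holm-Sidak-corrected Welch significance of x vs y:

    * unaffected: not S(disease,CT) and not S(treated,CT)
    * completely_treated: S(disease,CT) and not S(treated,CT)
    * untreated: S(disease,CT) and S(treated,CT) and not S(treated,disease)
    * partially_treated: all three significant and the treated mean lies
      strictly between the disease and CT means
    * treat_associated: every remaining case where the treated group
      differs from CT or from the disease group without tracking toward CT

    Columns are features; the correction family is the full feature set
    within each pairwise comparison.
    """
    ct = np.atleast_2d(np.asarray(ct, float))
    disease = np.atleast_2d(np.asarray(disease, float))
    treated = np.atleast_2d(np.asarray(treated, float))
    n_feat = ct.shape[1]
    s_dc, p_dc, pc_dc = _welch_corrected(disease, ct, alpha)
    s_tc, p_tc, pc_tc = _welch_corrected(treated, ct, alpha)
    s_td, p_td, pc_td = _welch_corrected(treated, disease, alpha)
    m_ct, m_d, m_t = ct.mean(axis=0), disease.mean(axis=0), treated.mean(axis=0)
    between = (np.minimum(m_ct, m_d) < m_t) & (m_t < np.maximum(m_ct, m_d))

    cats = np.empty(n_feat, object)
    for i in range(n_feat):
        if not s_dc[i] and not s_tc[i]:
            cats[i] = "unaffected"
        elif s_dc[i] and not s_tc[i]:
            cats[i] = "completely_treated"
        elif s_dc[i] and s_tc[i] and not s_td[i]:
            cats[i] = "untreated"
        elif s_dc[i] and s_tc[i] and s_td[i] and between[i]:
            cats[i] = "partially_treated"
        else:
            cats[i] = "treat_associated"
    names = feature_names if feature_names is not None \
        else [f"f{i}" for i in range(n_feat)]
    return pd.DataFrame({
        "feature": names, "category": cats,
        "mean_ct": m_ct, "mean_disease": m_d, "mean_treated": m_t,
        "p_disease_vs_ct": p_dc, "p_corr_disease_vs_ct": pc_dc,
        "p_treated_vs_ct": p_tc, "p_corr_treated_vs_ct": pc_tc,
        "p_treated_vs_disease": p_td, "p_corr_treated_vs_disease": pc_td,
    })


class TreatmentResponseModel:
    """Model-style wrapper around the TRE categorisation.

    Built from per-group value matrices (rows animals, columns features);
    ``fit()`` runs the three Welch comparison batches and returns a ledger
    results object.
    """

    def __init__(self, ct, disease, treated, feature_names=None):
        self.ct = np.atleast_2d(np.asarray(ct, float))
        self.disease = np.atleast_2d(np.asarray(disease, float))
        self.treated = np.atleast_2d(np.asarray(treated, float))
        self.feature_names = feature_names

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, ct_group: str,
                           disease_group: str, treated_group: str,
                           features: list[str]):
        def block(g):
            return table.loc[table["group"] == g, features].to_numpy(float)
        return cls(block(ct_group), block(disease_group),
                   block(treated_group), feature_names=features)

    def fit(self, alpha: float = 0.05) -> "TreatmentLedgerResults":
        ledger = classify_tre(self.ct, self.disease, self.treated,
                              self.feature_names, alpha)
        return TreatmentLedgerResults(ledger=ledger, alpha=alpha)


@dataclass
class TreatmentLedgerResults:
    ledger: pd.DataFrame
    alpha: float

    def category_fractions(self) -> pd.Series:
        frac = self.ledger["category"].value_counts(normalize=True)
        return frac.reindex(TRE_CATEGORIES, fill_value=0.0)

    def summary(self) -> str:
        n = len(self.ledger)
        lines = [f"Treatment response evaluation ({n} features, "
                 f"alpha={self.alpha}, Holm-Sidak corrected)"]
        for cat, frac in self.category_fractions().items():
            lines.append(f"  {cat:<20} {frac * 100:5.1f}%")
        return "\n".join(lines)
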
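"""Case-control association statistics for alleles and haplotypes.

Single-stratum 1-df chi-square allele tests, Cochran-Mantel-Haenszel
stratified pooling, sample-size-weighted z-score meta-analysis, genomic
control, and a stepwise conditional logistic regression scan over SNP and
imputed-HLA dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationError",
    "AlleleCounts2x2",
    "AssociationResult",
    "StratifiedAssociation",
    "MetaResult",
    "MarkerFit",
    "RegressionScanResult",
    "counts_from_freqs",
    "allele_association",
    "haplotype_association",
    "cmh_combined",
    "meta_weighted_z",
    "genomic_inflation",
    "logistic_scan",
    "stepwise_conditional",
]

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = 0.45494

GENOME_WIDE_P = 5e-8


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleCounts2x2:
    """Carrier/non-carrier chromosome counts in cases and controls."""

    a: int  # carrier chromosomes, cases
    b: int  # non-carrier chromosomes, cases
    c: int  # carrier chromosomes, controls
    d: int  # non-carrier chromosomes, controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AssociationError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def freq_case(self) -> float:
        return self.a / (self.a + self.b) if self.a + self.b else np.nan

    @property
    def freq_ctrl(self) -> float:
        return self.c / (self.c + self.d) if self.c + self.d else np.nan


@dataclass
class AssociationResult:
    freq_case: float
    freq_ctrl: float
    chi2: float
    p: float
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    or_defined: bool = True

    def __post_init__(self) -> None:
        if self.or_defined and self.ci95 is not None:
            lo, hi = self.ci95
            if not lo <= self.odds_ratio <= hi:
                raise AssociationError("OR outside its CI")


@dataclass
class StratifiedAssociation:
    tables: list[AlleleCounts2x2]
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    chi2: float
    p: float
    or_defined: bool = True


@dataclass
class MetaResult:
    p_values: list[float]
    signs: list[int]
    sample_sizes: list[float]
    z_scores: list[float]
    z_combined: float
    p_combined: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def counts_from_freqs(
    freq_case: float, freq_ctrl: float, n_cases: int, n_controls: int
) -> AlleleCounts2x2:
    """Reconstruct chromosome counts from printed allele frequencies."""
    if not (0 <= freq_case <= 1 and 0 <= freq_ctrl <= 1):
        raise AssociationError("frequencies must be in [0, 1]")
    a = _round_half_up(freq_case * 2 * n_cases)
    c = _round_half_up(freq_ctrl * 2 * n_controls)
    return AlleleCounts2x2(a, 2 * n_cases - a, c, 2 * n_controls - c)


def allele_association(table: AlleleCounts2x2) -> AssociationResult:
    """Pearson 1-df chi-square (no continuity correction) with Woolf CI OR."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
        p = float(stats.chi2.sf(chi2, df=1))
    if min(a, b, c, d) > 0:
        or_ = a * d / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.isf(0.025)
        ci = (float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se)))
        return AssociationResult(
            table.freq_case, table.freq_ctrl, float(chi2), p, float(or_), ci
        )
    return AssociationResult(
        table.freq_case, table.freq_ctrl, float(chi2), p, None, None, or_defined=False
    )


def haplotype_association(
    labels: np.ndarray, phenotype_per_chromosome: np.ndarray, focal: str
) -> AssociationResult:
    """Focal haplotype vs all others combined, delegated to the allele test."""
    labels = np.asarray(labels, dtype=object)
    case = np.asarray(phenotype_per_chromosome, dtype=bool)
    if labels.shape != case.shape:
        raise AssociationError("labels and phenotype must align per chromosome")
    hit = labels == focal
    if not hit.any():
        raise AssociationError(f"focal label {focal!r} absent")
    table = AlleleCounts2x2(
        a=int(np.sum(hit & case)),
        b=int(np.sum(~hit & case)),
        c=int(np.sum(hit & ~case)),
        d=int(np.sum(~hit & ~case)),
    )
    return allele_association(table)


def cmh_combined(tables: list[AlleleCounts2x2]) -> StratifiedAssociation:
    """Cochran-Mantel-Haenszel common odds ratio with RBG 95% CI.

    OR = sum(a_i d_i / N_i) / sum(b_i c_i / N_i); the CI uses the
    Robins-Breslow-Greenland variance of log OR.
    """
    if not tables:
        raise AssociationError("at least one stratum required")
    R = np.array([t.a * t.d / t.n for t in tables])
    S = np.array([t.b * t.c / t.n for t in tables])
    # CMH test statistic (1 df, no continuity correction)
    num = sum(t.a - (t.a + t.b) * (t.a + t.c) / t.n for t in tables)
    var = sum(
        (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d) / (t.n**2 * (t.n - 1))
        for t in tables
        if t.n > 1
    )
    chi2 = float(num**2 / var) if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    if R.sum() <= 0 or S.sum() <= 0:
        return StratifiedAssociation(tables, None, None, chi2, p, or_defined=False)
    or_ = float(R.sum() / S.sum())
    P = np.array([(t.a + t.d) / t.n for t in tables])
    Q = np.array([(t.b + t.c) / t.n for t in tables])
    var_log = (
        np.sum(P * R) / (2 * R.sum() ** 2)
        + np.sum(P * S + Q * R) / (2 * R.sum() * S.sum())
        + np.sum(Q * S) / (2 * S.sum() ** 2)
    )
    z = stats.norm.isf(0.025)
    se = float(np.sqrt(var_log))
    ci = (or_ * float(np.exp(-z * se)), or_ * float(np.exp(z * se)))
    return StratifiedAssociation(tables, or_, ci, chi2, p)


def meta_weighted_z(
    p_values: list[float], signs: list[int], sample_sizes: list[float]
) -> MetaResult:
    """Sample-size-weighted z-score meta-analysis.

    z_i is the signed two-tailed inverse-normal of p_i; the combined score
    is sum(z_i * sqrt(N_i)) / sqrt(sum N_i), converted back to a two-tailed
    p value.
    """
    if not (len(p_values) == len(signs) == len(sample_sizes)):
        raise AssociationError("inputs must have equal length")
    zs = []
    for p, s in zip(p_values, signs):
        if not 0 < p <= 1:
            raise AssociationError(f"p value {p} outside (0, 1]; supply z directly")
        if s not in (-1, 1):
            raise AssociationError("signs must be +/-1")
        zs.append(float(s * stats.norm.isf(p / 2)))
    w = np.sqrt(np.asarray(sample_sizes, dtype=float))
    z_comb = float(np.sum(np.array(zs) * w) / np.sqrt(np.sum(np.square(w))))
    p_comb = float(2 * stats.norm.sf(abs(z_comb)))
    return MetaResult(list(p_values), list(signs), list(sample_sizes), zs, z_comb, p_comb)


def genomic_inflation(chi2_values: np.ndarray, min_values: int = 100) -> float:
    """Genomic-control lambda: median chi-square over the 1-df null median."""
    x = np.asarray(chi2_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_values:
        raise AssociationError(
            f"need at least {min_values} chi-square values, got {x.size}"
        )
    return float(np.median(x) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# logistic regression scan


@dataclass
class MarkerFit:
    name: str
    beta: float | None
    se: float | None
    p: float | None
    converged: bool = True
    collinear: bool = False
    separated: bool = False

    @property
    def usable(self) -> bool:
        return (
            self.p is not None
            and self.converged
            and not self.collinear
            and not self.separated
        )


@dataclass
class RegressionScanResult:
    fits: list[MarkerFit]
    covariates: list[str] = field(default_factory=list)
    lambda_gc: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker": f.name,
                    "beta": f.beta,
                    "se": f.se,
                    "p": f.p,
                    "converged": f.converged,
                    "collinear": f.collinear,
                    "separated": f.separated,
                }
                for f in self.fits
            ]
        )


def _is_collinear(x: np.ndarray, design: np.ndarray) -> bool:
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    denom = float(np.var(x))
    if denom == 0:
        return True
    return float(np.sum(resid**2)) / (len(x) * denom) < 1e-10


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS logistic fit; returns (beta, se, converged)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100, method="newton")
        except Exception:
            return np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan), False
    conv = bool(res.mle_retvals.get("converged", False))
    return np.asarray(res.params), np.asarray(res.bse), conv


def logistic_scan(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    marker_names: list[str] | None = None,
    covariate_names: list[str] | None = None,
    compute_lambda: bool = False,
) -> RegressionScanResult:
    """Per-marker logistic regression of disease status on allele dosage.

    Each column of ``dosages`` (codes 0/1/2) is tested in the model
    ``phenotype ~ intercept + marker + covariates`` with a Wald p value on
    the marker term.  Markers collinear with the covariates are flagged and
    reported without a p value; separation and non-convergence are flagged.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise AssociationError("phenotype must be binary 0/1")
    n, p = D.shape
    names = marker_names or [f"m{j}" for j in range(p)]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    base = np.column_stack([np.ones(n), C])

    fits: list[MarkerFit] = []
    for j in range(p):
        x = D[:, j]
        if _is_collinear(x, base):
            fits.append(MarkerFit(names[j], None, None, None, collinear=True))
            continue
        X = np.column_stack([base, x])
        beta, se, conv = _fit_logistic(y, X)
        b, s = float(beta[-1]), float(se[-1])
        if not conv or not np.isfinite(b) or not np.isfinite(s):
            fits.append(MarkerFit(names[j], None, None, None, converged=False))
            continue
        if abs(b) > 15 or s > 100:
            fits.append(
                MarkerFit(names[j], b, s, None, separated=True)
            )
            continue
        wald_p = float(2 * stats.norm.sf(abs(b / s)))
        fits.append(MarkerFit(names[j], b, s, wald_p))
    lam = None
    if compute_lambda:
        chis = [
            (f.beta / f.se) ** 2 for f in fits if f.usable and f.se not in (None, 0)
        ]
        try:
            lam = genomic_inflation(np.array(chis))
        except AssociationError:
            lam = None
    return RegressionScanResult(
        fits, covariates=list(covariate_names or []), lambda_gc=lam
    )


def stepwise_conditional(
    cohorts: dict[str, dict],
    marker_names: list[str],
    threshold: float = GENOME_WIDE_P,
    max_steps: int = 20,
    selectable: list[str] | None = None,
) -> dict:
    """Stepwise forward conditional scan across cohorts with meta-combining.

    ``cohorts`` maps cohort name to ``{"dosages": (n, p), "phenotype": (n,)}``
    over a shared marker order.  At each step every remaining marker is
    tested per cohort conditional on the selected covariate dosages; per-
    marker p values are meta-combined with sample-size weights (direction
    from the sign of beta, relative to the first cohort); the top marker is
    added while its combined p stays below ``threshold``.

    ``selectable`` optionally restricts which markers may enter the
    conditioning sequence (all markers are still scanned at every step) —
    the stepwise procedure this mirrors conditions on imputed HLA
    allele/haplotype genotypes only, while SNPs are merely tested.

    Returns a dict with the ordered ``selected`` markers, their combined
    p values at selection, and per-step combined scans (marker -> p).
    """
    if not marker_names:
        raise AssociationError("empty marker set")
    order = {nm: j for j, nm in enumerate(marker_names)}
    pool = set(marker_names if selectable is None else selectable)
    unknown = pool - set(marker_names)
    if unknown:
        raise AssociationError(f"selectable markers not in marker set: {sorted(unknown)}")
    selected: list[str] = []
    selected_p: list[float] = []
    scans: list[dict[str, float]] = []
    for _step in range(max_steps):
        combined: dict[str, float] = {}
        remaining = [nm for nm in marker_names if nm not in selected]
        per_cohort: dict[str, RegressionScanResult] = {}
        for cname, data in cohorts.items():
            D = np.asarray(data["dosages"], dtype=float)
            y = np.asarray(data["phenotype"], dtype=float)
            cov = (
                D[:, [order[s] for s in selected]] if selected else None
            )
            per_cohort[cname] = logistic_scan(
                D[:, [order[nm] for nm in remaining]],
                y,
                covariates=cov,
                marker_names=remaining,
                covariate_names=selected,
            )
        sizes = {c: len(d["phenotype"]) for c, d in cohorts.items()}
        for k, nm in enumerate(remaining):
            ps, signs, ns = [], [], []
            for cname, scan in per_cohort.items():
                fit = scan.fits[k]
                if fit.usable:
                    ps.append(max(fit.p, 1e-300))
                    signs.append(1 if fit.beta >= 0 else -1)
                    ns.append(sizes[cname])
            if ps:
                combined[nm] = meta_weighted_z(ps, signs, ns).p_combined
        scans.append(combined)
        candidates = {nm: p for nm, p in combined.items() if nm in pool}
        if not candidates:
            break
        top = min(candidates, key=lambda nm: (candidates[nm], nm))
        if candidates[top] >= threshold:
            break
        selected.append(top)
        selected_p.append(combined[top])
    return {"selected": selected, "selected_p": selected_p, "scans": scans}
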
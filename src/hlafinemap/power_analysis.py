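"""Single-stage case-control power under a multiplicative disease model.

The per-copy genotype relative risk (GRR) is equated with the allele odds
ratio (a standard rare-disease multiplicative approximation); expected
case/control allele frequencies follow from Hardy-Weinberg genotype
frequencies and calibrated penetrances, and power is the normal
approximation to the two-sided 1-df allele (chromosome-count) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerError",
    "DiseaseModel",
    "DEFAULT_ALPHAS",
    "grr_from_observed",
    "expected_case_control_freqs",
    "power_single_stage",
    "power_table",
]

DEFAULT_ALPHAS = (0.05, 0.01, 5e-5, 5e-8)


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseModel:
    """Multiplicative risk model for one biallelic risk variant.

    Penetrances are ``f0``, ``f0*r`` and ``f0*r**2`` for 0/1/2 risk-allele
    copies, with ``f0`` calibrated so that the population prevalence under
    Hardy-Weinberg genotype frequencies equals ``prevalence`` exactly.
    """

    freq: float  # population risk-allele frequency
    grr: float  # per-copy relative risk
    prevalence: float = 0.002

    def __post_init__(self) -> None:
        if not 0 < self.freq < 1:
            raise PowerError("freq must be in (0, 1)")
        if self.grr <= 0:
            raise PowerError("grr must be positive")
        if not 0 < self.prevalence < 1:
            raise PowerError("prevalence must be in (0, 1)")
        if max(self.penetrances) > 1:
            raise PowerError("penetrance exceeds 1; model invalid")

    @property
    def genotype_freqs(self) -> np.ndarray:
        p = self.freq
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])

    @property
    def f0(self) -> float:
        p, r = self.freq, self.grr
        return self.prevalence / ((1 - p) ** 2 + 2 * p * (1 - p) * r + p**2 * r**2)

    @property
    def penetrances(self) -> tuple[float, float, float]:
        f0 = self.f0
        return (f0, f0 * self.grr, f0 * self.grr**2)


def grr_from_observed(freq_case: float, freq_ctrl: float) -> float:
    """GRR as the allele odds ratio of observed case/control frequencies.

    Valid under multiplicative risk and rare disease (documented
    approximation).
    """
    for f in (freq_case, freq_ctrl):
        if not 0 < f < 1:
            raise PowerError(f"frequency {f} must be strictly inside (0, 1)")
    return (freq_case / (1 - freq_case)) / (freq_ctrl / (1 - freq_ctrl))


def expected_case_control_freqs(model: DiseaseModel) -> tuple[float, float]:
    """Expected case/control risk-allele frequencies via Bayes from HWE."""
    g = model.genotype_freqs
    f = np.array(model.penetrances)
    k = float(g @ f)
    case_g = g * f / k
    ctrl_g = g * (1 - f) / (1 - k)
    freq_case = float(case_g[1] / 2 + case_g[2])
    freq_ctrl = float(ctrl_g[1] / 2 + ctrl_g[2])
    return freq_case, freq_ctrl


def power_single_stage(
    n_cases: int, n_controls: int, model: DiseaseModel, alpha: float
) -> float:
    """Analytic power of the two-sided 1-df allele test (2n chromosomes).

    Normal approximation: the rejection threshold uses the pooled-frequency
    null standard error and the shift uses the alternative standard error.
    """
    if not 0 < alpha < 1:
        raise PowerError("alpha must be in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise PowerError("sample sizes must be positive")
    p1, p0 = expected_case_control_freqs(model)
    n1, n0 = 2 * n_cases, 2 * n_controls
    delta = abs(p1 - p0)
    pbar = (p1 * n1 + p0 * n0) / (n1 + n0)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    za = stats.norm.isf(alpha / 2)
    power = stats.norm.sf((za * se0 - delta) / se1) + stats.norm.sf(
        (za * se0 + delta) / se1
    )
    return float(np.clip(power, 0.0, 1.0))


def power_table(
    rows: list[dict],
    n_cases: int,
    n_controls: int,
    prevalence: float = 0.002,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
) -> pd.DataFrame:
    """Power to detect recombinant haplotypes at the extended lineage's GRR.

    Each row supplies ``name``, the extended lineage's observed
    ``ext_freq_case``/``ext_freq_ctrl`` (or a precomputed ``grr``) and the
    recombinant lineage's control frequency ``rec_freq_ctrl``.  Rows with
    missing frequencies are skipped with a warning column.
    """
    out = []
    for row in rows:
        rec = {"name": row.get("name", "?")}
        try:
            if "grr" in row and row["grr"] is not None:
                r = float(row["grr"])
            else:
                r = grr_from_observed(row["ext_freq_case"], row["ext_freq_ctrl"])
            p = float(row["rec_freq_ctrl"])
            model = DiseaseModel(freq=p, grr=r, prevalence=prevalence)
        except (KeyError, TypeError, PowerError) as exc:
            rec["skipped"] = str(exc)
            out.append(rec)
            continue
        rec.update({"rec_freq_ctrl": p, "grr": r, "skipped": ""})
        for alpha in alphas:
            rec[f"power_at_{alpha:g}"] = power_single_stage(
                n_cases, n_controls, model, alpha
            )
        out.append(rec)
    return pd.DataFrame(out)
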
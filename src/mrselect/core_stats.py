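"""Closed-form statistics for single-instrument two-sample MR.

Everything here works on the "chi-square scale": an association is carried
as the 1-df Wald statistic ``W = (beta_hat / se)**2``, and every p-value is
the 1-df chi-square upper tail (equivalently a two-sided normal tail).

The module provides the SMR test ``T = Wgx*Wgy/(Wgx+Wgy)``, the more
powerful min-test ``min{Wgx, Wgy}``, the conditional test (test ``Wgy``
alone, given the instrument already passed exposure selection, with a
gene-level Bonferroni correction), and the two-sample MR Steiger test on
Fisher-Z-transformed absolute correlations.

The conditional test assumes the instrument is valid (no pleiotropy: the
SNP affects the trait only through the exposure). That assumption is
documented, not checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "AssocSummary",
    "SelectionDesign",
    "SMRResult",
    "SteigerResult",
    "wald_chisq",
    "chisq_upper_p",
    "p_to_chisq_threshold",
    "wald_to_min_abs_corr",
    "fisher_z",
    "fisher_z_signed",
    "wald_ratio",
    "smr_statistic",
    "min_test",
    "conditional_test",
    "steiger_test",
]

GENOME_WIDE_P = 5e-8


def wald_chisq(beta_hat: float, se: float) -> float:
    """Wald statistic ``(beta_hat/se)**2`` on the 1-df chi-square scale.

    Parameters
    ----------
    beta_hat : float
        Per-allele effect estimate.
    se : float
        Its standard error; must be positive.
    """
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return (beta_hat / se) ** 2


def chisq_upper_p(w) -> float:
    """Upper-tail probability of the 1-df chi-square at ``w``.

    Equals the two-sided standard-normal p-value of ``sqrt(w)``.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("Wald statistic must be non-negative")
    out = stats.chi2.sf(w, df=1)
    return float(out) if out.ndim == 0 else out


def p_to_chisq_threshold(p: float) -> float:
    """1-df chi-square cutoff whose upper tail is ``p`` (inverse of
    :func:`chisq_upper_p`).

    ``p = 5e-8`` gives the genome-wide Wald cutoff 29.71679.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return float(stats.chi2.isf(p, df=1))


def wald_to_min_abs_corr(w_threshold: float, n: int) -> float:
    """Smallest |sample correlation| compatible with a Wald cutoff.

    Uses ``|rho| = 1/sqrt(1 + (n-2)/W)``, the exact relation between the
    simple-regression Wald statistic and the sample correlation.
    """
    if w_threshold <= 0:
        raise ValueError("Wald threshold must be positive")
    if n < 3:
        raise ValueError(f"sample size must be >= 3, got {n}")
    return 1.0 / math.sqrt(1.0 + (n - 2) / w_threshold)


def fisher_z(rho) -> float:
    """Fisher-Z transform of ``|rho|``: ``0.5*ln((1+|rho|)/(1-|rho|))``.

    The absolute value matches the MR Steiger convention, where only the
    magnitude of the SNP-trait correlation is compared; use
    :func:`fisher_z_signed` for the classical signed transform.
    """
    return fisher_z_signed(np.abs(rho))


def fisher_z_signed(rho) -> float:
    """Signed Fisher-Z transform ``arctanh(rho)``; odd in ``rho``."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    out = np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


def wald_ratio(b_gy_hat: float, b_gx_hat: float) -> float:
    """Single-instrument causal-effect estimate ``b_gy_hat / b_gx_hat``.

    This is the 2SLS / Wald-ratio estimate of the effect of the exposure on
    the trait. A zero exposure effect makes the instrument degenerate.
    """
    if b_gx_hat == 0:
        raise ZeroDivisionError(
            "exposure effect b_gx_hat is zero: the Wald ratio is undefined "
            "(weak-instrument degenerate case)"
        )
    return b_gy_hat / b_gx_hat


@dataclass(frozen=True)
class AssocSummary:
    """One SNP-trait association record from a GWAS summary table."""

    snp_id: str
    beta_hat: float
    se: float
    p: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.n is not None and self.n < 4:
            raise ValueError(f"{self.snp_id}: sample size must be >= 4, got {self.n}")
        if self.p is not None:
            if not (0 < self.p <= 1):
                raise ValueError(f"{self.snp_id}: p must be in (0, 1], got {self.p}")
            implied = chisq_upper_p(self.wald)
            if not math.isclose(self.p, implied, rel_tol=1e-6):
                raise ValueError(
                    f"{self.snp_id}: p={self.p} inconsistent with Wald statistic "
                    f"(implies p={implied:.6g})"
                )

    @property
    def wald(self) -> float:
        return wald_chisq(self.beta_hat, self.se)

    @property
    def p_value(self) -> float:
        return self.p if self.p is not None else chisq_upper_p(self.wald)

    def abs_corr(self) -> float:
        """|sample correlation| implied by the Wald statistic at size n."""
        if self.n is None:
            raise ValueError(f"{self.snp_id}: sample size required")
        w = self.wald
        if w == 0:
            return 0.0
        return wald_to_min_abs_corr(w, self.n)


@dataclass(frozen=True)
class SelectionDesign:
    """Instrument-selection rule and the cutoffs it implies.

    A p-value threshold (default genome-wide, 5e-8) determines a Wald
    cutoff on the chi-square scale, a per-sample-size floor on the
    attainable |sample correlation|, and the corresponding Fisher-Z floor —
    the truncation points under which every downstream statistic operates.
    """

    p_threshold: float = GENOME_WIDE_P
    w_threshold: float = field(init=False)

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        object.__setattr__(self, "w_threshold", p_to_chisq_threshold(self.p_threshold))

    def min_abs_corr(self, n: int) -> float:
        """Smallest selectable |correlation| at sample size ``n``."""
        return wald_to_min_abs_corr(self.w_threshold, n)

    def fisher_z_cutoff(self, n: int) -> float:
        """Left-truncation point on the Fisher-Z scale at sample size ``n``."""
        return fisher_z(self.min_abs_corr(n))


@dataclass(frozen=True)
class SMRResult:
    """SMR test output plus the min-test and conditional-test p-values."""

    t_smr: float
    p_smr: float
    b_xy_hat: float | None
    t_min: float
    p_min: float
    p_conditional: float


def smr_statistic(w_gx: float, w_gy: float) -> tuple[float, float]:
    """SMR statistic ``Wgx*Wgy/(Wgx+Wgy)`` and its 1-df chi-square p-value.

    The statistic is half the harmonic mean of the two Wald statistics, so
    it is strictly below ``min(Wgx, Wgy)`` whenever both are positive —
    referring it to a 1-df chi-square gives a conservative test. The
    both-zero corner returns (0, 1), the limit along ``w_gx = w_gy -> 0``.
    """
    if w_gx < 0 or w_gy < 0:
        raise ValueError("Wald statistics must be non-negative")
    if w_gx == 0 and w_gy == 0:
        return 0.0, 1.0
    t = w_gx * w_gy / (w_gx + w_gy)
    return t, chisq_upper_p(t)


def min_test(w_gx: float, w_gy: float) -> tuple[float, float]:
    """Min-test: statistic ``min{Wgx, Wgy}``, p = max of the marginal
    p-values, so rejection at level alpha happens iff both marginals reject.
    """
    if w_gx < 0 or w_gy < 0:
        raise ValueError("Wald statistics must be non-negative")
    t = min(w_gx, w_gy)
    p = max(chisq_upper_p(w_gx), chisq_upper_p(w_gy))
    return t, p


def conditional_test(
    w_gy: float, m_genes: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Conditional test of the trait association at an already-selected
    instrument.

    Because the SNP was selected for genome-wide-significant association
    with the exposure, ``b_gx = 0`` is excluded and the causal null reduces
    (under instrument validity) to ``b_gy = 0``, tested by ``Wgy`` alone.
    Multiplicity is corrected only over the ``m_genes`` genes that carry a
    selected instrument: rejection requires ``p < alpha / m_genes``
    (strict inequality).

    Returns
    -------
    (p, threshold, reject)
    """
    if m_genes < 1:
        raise ValueError(f"number of genes must be >= 1, got {m_genes}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if w_gy < 0:
        raise ValueError("Wald statistic must be non-negative")
    p = chisq_upper_p(w_gy)
    threshold = alpha / m_genes
    return p, threshold, p < threshold


def smr_with_alternatives(
    w_gx: float,
    w_gy: float,
    b_gx_hat: float | None = None,
    b_gy_hat: float | None = None,
    m_genes: int = 1,
    alpha: float = 0.05,
) -> SMRResult:
    """Bundle SMR, min-test and conditional-test results for one instrument."""
    t_smr, p_smr = smr_statistic(w_gx, w_gy)
    t_min, p_min = min_test(w_gx, w_gy)
    p_cond, _, _ = conditional_test(w_gy, m_genes, alpha)
    b_xy = None
    if b_gx_hat is not None and b_gy_hat is not None and b_gx_hat != 0:
        b_xy = wald_ratio(b_gy_hat, b_gx_hat)
    return SMRResult(t_smr, p_smr, b_xy, t_min, p_min, p_cond)


Direction = Literal["x_to_y", "y_to_x", "undetermined"]


@dataclass(frozen=True)
class SteigerResult:
    """Two-sample MR Steiger test output."""

    t_steiger: float
    p: float
    direction: Direction
    z_gx: float
    z_gy: float


def steiger_test(
    rho_gx_hat: float,
    rho_gy_hat: float,
    n_x: int,
    n_y: int,
    alpha: float = 0.05,
) -> SteigerResult:
    """Two-sample MR Steiger directionality test.

    Compares Fisher-Z transforms of the |sample correlations| of the SNP
    with exposure and trait:

        T = (z_gx - z_gy) / sqrt(1/(n_x-3) + 1/(n_y-3))

    referred to N(0, 1). Significant and positive means the causal
    direction is exposure -> trait; significant and negative the reverse;
    otherwise undetermined. Note the N(0,1) reference is only valid for
    unselected instruments — under genome-wide selection the z's are
    truncated and the test can be liberal or conservative.
    """
    if n_x < 4 or n_y < 4:
        raise ValueError("sample sizes must be >= 4")
    z_gx = fisher_z(rho_gx_hat)
    z_gy = fisher_z(rho_gy_hat)
    denom = math.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    t = (z_gx - z_gy) / denom
    p = 2.0 * stats.norm.sf(abs(t))
    if p < alpha:
        direction: Direction = "x_to_y" if t > 0 else "y_to_x"
    else:
        direction = "undetermined"
    return SteigerResult(t, p, direction, z_gx, z_gy)


def steiger_test_from_z(
    z_gx, z_gy, n_x: int, n_y: int
):
    """Vectorised Steiger statistic from already-transformed Fisher-Z values."""
    if n_x < 4 or n_y < 4:
        raise ValueError("sample sizes must be >= 4")
    z_gx = np.asarray(z_gx, dtype=float)
    z_gy = np.asarray(z_gy, dtype=float)
    denom = math.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    return (z_gx - z_gy) / denom
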
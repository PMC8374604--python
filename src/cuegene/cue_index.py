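"""The CUE_gene index: a transcript-based proxy for carbon-use efficiency.

Combining the growth and respiration power laws (mu = e^a1 * GT48^b1,
qCO2 = e^a2 * KGD^b2) through CUE = mu/(mu + qCO2) gives

    CUE_gene = e^a1 GT48^b1 / (e^a1 GT48^b1 + e^a2 KGD^b2)
             = (1 + C * KGD^b2 / GT48^b1)^-1,   C = e^(a2 - a1).

The compact constant C summarizes the two intercepts.  The index is
re-fitted per dataset: the coefficients depend on the normalization
basis of the expression data and do not transfer between studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markers import MarkerModel, fit_linear, predict_rate

__all__ = [
    "CueIndexModel",
    "build_index",
    "cue_gene",
    "cue_gene_explicit",
    "simple_ratio",
    "evaluate_index",
]


@dataclass(frozen=True)
class CueIndexModel:
    """Paired growth/respiration marker models and the compact constant."""

    growth_model: MarkerModel
    resp_model: MarkerModel
    compact_constant: float

    def __post_init__(self) -> None:
        expected = math.exp(self.resp_model.alpha - self.growth_model.alpha)
        if not math.isclose(self.compact_constant, expected, rel_tol=1e-12):
            raise ValueError("compact_constant inconsistent with stored intercepts")


def build_index(growth_model: MarkerModel, resp_model: MarkerModel) -> CueIndexModel:
    """Pair a growth and a respiration marker model into an index.

    The models must target different responses (growth rate vs metabolic
    quotient); passing two fits of the same response is an error.
    """
    if growth_model.response_label == resp_model.response_label:
        raise ValueError(
            "growth and respiration models share response label "
            f"{growth_model.response_label!r}"
        )
    constant = math.exp(resp_model.alpha - growth_model.alpha)
    return CueIndexModel(growth_model, resp_model, constant)


def cue_gene(index: CueIndexModel, gt48: float, kgd: float) -> float:
    """Index value (1 + C * KGD^b2 / GT48^b1)^-1, strictly in (0, 1).

    Algebraically identical to mu_hat / (mu_hat + q_hat) with the two
    power-law predictions; increasing in the growth marker and decreasing
    in the respiration marker when both slopes are positive.
    """
    if gt48 <= 0 or kgd <= 0:
        raise ValueError("marker expression must be > 0")
    ratio = (
        index.compact_constant
        * kgd**index.resp_model.beta
        / gt48**index.growth_model.beta
    )
    return 1.0 / (1.0 + ratio)


def cue_gene_explicit(index: CueIndexModel, gt48: float, kgd: float) -> float:
    """Index via the explicit flux-ratio form mu_hat/(mu_hat + q_hat).

    Kept separate from :func:`cue_gene` so the algebraic identity between
    the two forms can be verified rather than assumed.
    """
    mu_hat = predict_rate(index.growth_model, gt48)
    q_hat = predict_rate(index.resp_model, kgd)
    return mu_hat / (mu_hat + q_hat)


def simple_ratio(gt48: float, kgd: float) -> float:
    """Plain expression ratio GT48/KGD, a coarser indicator of CUE."""
    if kgd <= 0:
        raise ValueError("kgd must be > 0")
    return gt48 / kgd


def evaluate_index(cue_gene_values, measured_cue) -> MarkerModel:
    """Regress measured CUE on the gene index (untransformed scales).

    Both inputs are per-sample values in (0, 1); returns the OLS fit
    (intercept alpha, slope beta, R^2, residual SE, F).
    """
    x = np.asarray(cue_gene_values, dtype=float)
    y = np.asarray(measured_cue, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    return fit_linear(x, y, response_label="cue", marker_label="cue_gene")
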
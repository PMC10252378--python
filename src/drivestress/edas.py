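"""EDAS (Evaluation based on Distance from Average Solution) model ranking.

The procedure scores each alternative (here: a trained stress classifier)
against the per-criterion average of all alternatives and ranks by the
combined normalized distance, in eight steps:

1. per-criterion averages ψ_β (column means);
2.–3. positive and negative distance matrices — for a beneficial criterion
   the *positive* distance is the shortfall below average,
   PI_αβ = max(0, ψ_β − X_αβ)/ψ_β, and the *negative* distance the surplus
   above it, NI_αβ = max(0, X_αβ − ψ_β)/ψ_β; a non-beneficial criterion
   swaps the two;
4.–5. weighted sums SPI_α = Σ_β y_β PI_αβ and SNI_α = Σ_β y_β NI_αβ;
6. normalization NSPI_α = SPI_α / max SPI and NSNI_α = 1 − SNI_α / max SNI
   (a zero maximum makes the ratio zero);
7. appraisal score λ_α = (NSPI_α + NSNI_α) / 2 ∈ [0, 1];
8. dense ranking with the *lowest* λ ranked first.

With this orientation a model penalized little for under-average criteria
and rewarded much for above-average ones gets λ near 0 and rank 1; the
resulting order coincides with conventional EDAS (where the appraisal score
is maximized).  The method is often called "fuzzy EDAS" in the application
literature even when, as here, the inputs are crisp numbers; no
fuzzification is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from drivestress.errors import EmptyInputError

__all__ = [
    "DecisionMatrix",
    "EdasResult",
    "average_solution",
    "distance_matrices",
    "weighted_sums",
    "normalize_sums",
    "appraisal",
    "rank",
    "run_edas",
    "DEFAULT_TIE_TOL",
]

#: Default tie tolerance: half of one 4-decimal rounding step.
DEFAULT_TIE_TOL = 5e-5


@dataclass
class DecisionMatrix:
    """Alternatives × criteria values with weights and benefit flags."""

    x: np.ndarray
    weights: np.ndarray
    beneficial: np.ndarray
    names: tuple = ()
    criteria: tuple = ()

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        m = self.x.shape[1]
        self.weights = np.asarray(self.weights, dtype=float)
        self.beneficial = np.asarray(self.beneficial, dtype=bool)
        if self.x.size == 0:
            raise EmptyInputError("decision matrix is empty")
        if self.weights.shape != (m,):
            raise ValueError(f"expected {m} weights, got {self.weights.shape}")
        if self.beneficial.shape != (m,):
            raise ValueError(f"expected {m} benefit flags")
        if (self.weights <= 0).any():
            raise ValueError("criteria weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-3:
            warnings.warn(
                f"criteria weights sum to {self.weights.sum():.6f}, not 1", stacklevel=2
            )
        if not self.names:
            self.names = tuple(f"A{i + 1}" for i in range(self.x.shape[0]))
        if not self.criteria:
            self.criteria = tuple(f"C{j + 1}" for j in range(m))
        if len(self.names) != self.x.shape[0] or len(self.criteria) != m:
            raise ValueError("names/criteria length mismatch")

    def renormalized(self) -> "DecisionMatrix":
        """Copy with weights rescaled to sum exactly to one (opt-in)."""
        return DecisionMatrix(
            x=self.x.copy(),
            weights=self.weights / self.weights.sum(),
            beneficial=self.beneficial.copy(),
            names=self.names,
            criteria=self.criteria,
        )


@dataclass
class EdasResult:
    """The full intermediate chain, kept for audit."""

    psi: np.ndarray
    pi: np.ndarray
    ni: np.ndarray
    spi: np.ndarray
    sni: np.ndarray
    nspi: np.ndarray
    nsni: np.ndarray
    lam: np.ndarray
    ranks: np.ndarray
    names: tuple
    criteria: tuple

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "criteria": list(self.criteria),
            "psi": self.psi.tolist(),
            "PI": self.pi.tolist(),
            "NI": self.ni.tolist(),
            "SPI": self.spi.tolist(),
            "SNI": self.sni.tolist(),
            "NSPI": self.nspi.tolist(),
            "NSNI": self.nsni.tolist(),
            "appraisal": self.lam.tolist(),
            "ranks": self.ranks.tolist(),
        }


def average_solution(x: np.ndarray) -> np.ndarray:
    """Step 1: per-criterion column means ψ_β."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.size == 0:
        raise EmptyInputError("empty matrix has no average solution")
    return x.mean(axis=0)


def distance_matrices(x: np.ndarray, psi: np.ndarray, beneficial) -> tuple:
    """Steps 2–3: relative positive/negative distances from the average.

    For beneficial criteria PI is the shortfall below ψ and NI the surplus
    above it; non-beneficial criteria swap the two.  PI·NI = 0 elementwise.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    psi = np.asarray(psi, dtype=float)
    beneficial = np.asarray(beneficial, dtype=bool)
    if (psi == 0).any():
        raise ZeroDivisionError("a criterion average is zero; distances are undefined")
    below = np.maximum(0.0, psi - x) / psi
    above = np.maximum(0.0, x - psi) / psi
    pi = np.where(beneficial, below, above)
    ni = np.where(beneficial, above, below)
    return pi, ni


def weighted_sums(pi: np.ndarray, ni: np.ndarray, weights) -> tuple:
    """Steps 4–5: criterion-weighted sums SPI_α and SNI_α."""
    weights = np.asarray(weights, dtype=float)
    if pi.shape[1] != len(weights) or ni.shape[1] != len(weights):
        raise ValueError("weight length does not match the criteria count")
    return pi @ weights, ni @ weights


def normalize_sums(spi: np.ndarray, sni: np.ndarray) -> tuple:
    """Step 6: NSPI = SPI/max SPI and NSNI = 1 − SNI/max SNI.

    When a maximum is zero the ratio is defined as zero, so an all-zero SPI
    gives NSPI = 0 everywhere and an all-zero SNI gives NSNI = 1 everywhere.
    """
    spi = np.asarray(spi, dtype=float)
    sni = np.asarray(sni, dtype=float)
    max_spi, max_sni = spi.max(initial=0.0), sni.max(initial=0.0)
    nspi = spi / max_spi if max_spi > 0 else np.zeros_like(spi)
    nsni = 1.0 - (sni / max_sni if max_sni > 0 else np.zeros_like(sni))
    return nspi, nsni


def appraisal(nspi: np.ndarray, nsni: np.ndarray) -> np.ndarray:
    """Step 7: λ_α = (NSPI_α + NSNI_α)/2, guaranteed in [0, 1]."""
    nspi = np.asarray(nspi, dtype=float)
    nsni = np.asarray(nsni, dtype=float)
    if nspi.shape != nsni.shape:
        raise ValueError("NSPI and NSNI differ in length")
    return 0.5 * (nspi + nsni)


def rank(lam: np.ndarray, tol: float = DEFAULT_TIE_TOL) -> np.ndarray:
    """Step 8: dense ranks, ascending λ; values within *tol* share a rank."""
    lam = np.asarray(lam, dtype=float)
    order = np.argsort(lam, kind="stable")
    ranks = np.empty(len(lam), dtype=int)
    current = 0
    cluster_ref = None
    for i in order:
        if cluster_ref is None or lam[i] - cluster_ref > tol:
            current += 1
            cluster_ref = lam[i]
        ranks[i] = current
    return ranks


def run_edas(dm: DecisionMatrix, tie_tol: float = DEFAULT_TIE_TOL) -> EdasResult:
    """Run the full eight-step chain and return every intermediate."""
    psi = average_solution(dm.x)
    pi, ni = distance_matrices(dm.x, psi, dm.beneficial)
    spi, sni = weighted_sums(pi, ni, dm.weights)
    nspi, nsni = normalize_sums(spi, sni)
    lam = appraisal(nspi, nsni)
    ranks = rank(lam, tol=tie_tol)
    return EdasResult(
        psi=psi, pi=pi, ni=ni, spi=spi, sni=sni, nspi=nspi, nsni=nsni,
        lam=lam, ranks=ranks, names=dm.names, criteria=dm.criteria,
    )
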
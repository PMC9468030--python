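"""Poisson model of droplet occupancy and bead-semibulk pairing efficiency.

In a droplet generator, beads and semibulks are loaded independently and the
number of objects per droplet is Poisson: p(k, λ) = λ^k e^{-λ} / k!, with λ
the mean number of objects per droplet set by the loading concentration.
Both loadings are kept at λ < 1 so that droplets rarely contain more than
one object of either kind; the probability that a droplet holds exactly one
bead AND one semibulk then approaches the product of the two λ values.

This module fits λ from observed occupancy tables (droplets counted by the
number of objects they contain) and evaluates the pairing efficiency both in
the small-λ approximation λ_s · λ_b and exactly as p(1, λ_s) · p(1, λ_b).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "OccupancyTable",
    "PoissonOccupancyModel",
    "PairingEfficiency",
    "poisson_pmf",
    "fit_lambda",
    "pairing_efficiency",
    "expected_occupancy_fractions",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 maps to 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def poisson_pmf(k, lambda_value: float):
    """Probability that a droplet contains exactly ``k`` objects.

    Evaluates λ^k e^{-λ} / k! in log space so large ``k`` does not overflow.
    Accepts scalar or array ``k``; λ = 0 returns the point mass at k = 0.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.all(np.equal(np.mod(k_arr, 1), 0)):
        raise ValueError("k must be a non-negative integer")
    if lambda_value < 0:
        raise ValueError("lambda must be non-negative")
    if lambda_value == 0:
        out = np.where(k_arr == 0, 1.0, 0.0)
    else:
        with np.errstate(divide="ignore"):
            log_p = (
                k_arr * np.log(lambda_value)
                - lambda_value
                - gammaln(k_arr + 1.0)
            )
        out = np.exp(log_p)
    return float(out) if np.isscalar(k) else out


@dataclass
class OccupancyTable:
    """Droplet counts indexed by the number of encapsulated objects.

    ``k_values`` must be contiguous from 0; the last category may be read as
    "k or more" by the truncation-aware least-squares fit.
    """

    k_values: np.ndarray
    droplet_counts: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.droplet_counts = np.asarray(self.droplet_counts, dtype=np.int64)
        if self.k_values.shape != self.droplet_counts.shape:
            raise ValueError("k_values and droplet_counts must align")
        if not np.array_equal(self.k_values, np.arange(len(self.k_values))):
            raise ValueError("k_values must be contiguous starting at 0")
        if np.any(self.droplet_counts < 0):
            raise ValueError("droplet counts must be non-negative")

    @property
    def n_droplets(self) -> int:
        return int(self.droplet_counts.sum())

    @property
    def kmax(self) -> int:
        return int(self.k_values[-1])

    def fractions(self) -> np.ndarray:
        n = self.n_droplets
        if n == 0:
            return np.zeros_like(self.droplet_counts, dtype=float)
        return self.droplet_counts / n

    # -- TSV interchange (`k<TAB>count` with header) ---------------------

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"k": self.k_values, "count": self.droplet_counts}).to_csv(
            path, sep="\t", index=False
        )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OccupancyTable":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("k")
        return cls(df["k"].to_numpy(), df["count"].to_numpy())


@dataclass
class PoissonOccupancyModel:
    """A fitted occupancy model: λ̂ plus pmf evaluation."""

    lambda_hat: float
    method: str = "mean"
    #: set when the fit degenerated (e.g. an all-zero table)
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.lambda_hat < 0:
            raise ValueError("lambda_hat must be non-negative")

    def pmf(self, k):
        return poisson_pmf(k, self.lambda_hat)


def fit_lambda(table: OccupancyTable, method: str = "mean") -> PoissonOccupancyModel:
    """Fit the Poisson mean λ from an occupancy table.

    ``method="mean"`` returns the occupancy-weighted sample mean
    Σ k·count_k / n — the Poisson MLE when the top category is not a binned
    tail.  ``method="least_squares"`` minimises the squared error between
    observed category fractions and the model fractions over k = 0..kmax,
    treating the top category as "kmax or more".
    """
    if table.n_droplets < 1:
        warnings.warn("occupancy table is empty; returning lambda = 0")
        return PoissonOccupancyModel(0.0, method=method, warning="empty_table")
    if method == "mean":
        lam = float(
            (table.k_values * table.droplet_counts).sum() / table.n_droplets
        )
        warning = None
        if lam == 0.0:
            warning = "all_droplets_empty"
        return PoissonOccupancyModel(lam, method="mean", warning=warning)
    if method == "least_squares":
        obs = table.fractions()
        kmax = table.kmax

        def model_fractions(lam: float) -> np.ndarray:
            p = poisson_pmf(np.arange(kmax + 1), lam)
            p[kmax] = max(0.0, 1.0 - p[:kmax].sum())  # binned tail
            return p

        def loss(lam: float) -> float:
            return float(((obs - model_fractions(lam)) ** 2).sum())

        mean_lam = (table.k_values * table.droplet_counts).sum() / table.n_droplets
        upper = max(5.0, 4.0 * mean_lam + 1.0)
        res = minimize_scalar(
            loss, bounds=(0.0, upper), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(res.x)
        warning = "all_droplets_empty" if obs[0] == 1.0 else None
        if obs[0] == 1.0:
            lam = 0.0
        return PoissonOccupancyModel(lam, method="least_squares", warning=warning)
    raise ValueError(f"unknown method {method!r}; use 'mean' or 'least_squares'")


@dataclass(frozen=True)
class PairingEfficiency:
    """Probability that a droplet pairs one bead with one semibulk.

    ``approx`` is the small-λ product λ_s · λ_b used for back-of-envelope
    loading design; ``exact_single_single`` is p(1, λ_s) · p(1, λ_b), the
    exact probability of exactly-one-of-each.
    """

    lambda_semibulk: float
    lambda_bead: float
    approx: float
    exact_single_single: float

    def rounded(self, sig: int = 2) -> float:
        """The approximation at report precision (2 significant figures)."""
        return round_sig(self.approx, sig)

    def __float__(self) -> float:
        return self.approx


def pairing_efficiency(
    lambda_semibulk: float, lambda_bead: float
) -> PairingEfficiency:
    """Pairing efficiency of independent bead and semibulk encapsulation."""
    if lambda_semibulk < 0 or lambda_bead < 0:
        raise ValueError("lambda values must be non-negative")
    return PairingEfficiency(
        lambda_semibulk=lambda_semibulk,
        lambda_bead=lambda_bead,
        approx=lambda_semibulk * lambda_bead,
        exact_single_single=poisson_pmf(1, lambda_semibulk)
        * poisson_pmf(1, lambda_bead),
    )


def expected_occupancy_fractions(
    model: PoissonOccupancyModel, kmax: int
) -> np.ndarray:
    """Model fractions p(0..kmax, λ̂) plus a final tail-mass entry; sums to 1."""
    if kmax < 0:
        raise ValueError("kmax must be non-negative")
    p = model.pmf(np.arange(kmax + 1))
    tail = max(0.0, 1.0 - p.sum())
    return np.concatenate([p, [tail]])
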
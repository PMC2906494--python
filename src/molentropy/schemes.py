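"""Coefficient schemes for the information functionals.

One :class:`CoefficientScheme` bundles every tunable knob of the entropy
descriptors: the exponent base ``alpha`` of the sphere functionals, the
strictly decreasing sphere coefficients ``b_1 > ... > b_rho > 0``, the
per-element label weights ``w(l) > 0``, the normalised label-mix
coefficients ``c_l`` (summing to 1 over the alphabet in use), the numeric
values attached to bond-type edge labels, and the scaling constant
``lambda`` of the lambda-measure family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .masses import MASS_H, MASS_U, atomic_mass

#: numeric bond values: single 1, double 2, triple 3, aromatic 1.5
DEFAULT_EDGE_VALUES: dict[str, float] = {"s": 1.0, "d": 2.0, "t": 3.0, "ar": 1.5}


@dataclass(frozen=True)
class CoefficientScheme:
    """Parameter bundle for the entropy descriptors.

    Parameters
    ----------
    alpha:
        base of the exponential sphere functionals (> 0, != 1 useful).
    sphere_coeffs:
        ``"linear"``: ``b_j = rho - j + 1``; ``"exponential"``:
        ``b_j = 2**(rho - j)``.  Both strictly decreasing and positive.
    label_weight:
        per-element weight ``w(l)``: ``"mass"`` = m_l / m_U (hydrogen
        lightest, uranium heaviest), ``"inverse_mass"`` = m_H / m_l,
        ``"uniform"`` = 1.
    label_mix:
        normalised coefficients ``c_l`` over an alphabet ordered by
        ascending atomic mass (sentinel/unknown symbols sort last,
        alphabetically): ``"linear_rank"``: c_r proportional to K - r + 1;
        ``"exponential_rank"``: c_r proportional to 2**(-r).
    edge_values:
        numeric value per bond-type edge label.
    lam:
        scaling constant of the lambda-measure family (default 1000).
    """

    alpha: float = 2.0
    sphere_coeffs: str = "exponential"
    label_weight: str = "mass"
    label_mix: str = "exponential_rank"
    edge_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_VALUES)
    )
    lam: float = 1000.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.sphere_coeffs not in ("linear", "exponential"):
            raise ValueError(f"unknown sphere_coeffs {self.sphere_coeffs!r}")
        if self.label_weight not in ("mass", "inverse_mass", "uniform"):
            raise ValueError(f"unknown label_weight {self.label_weight!r}")
        if self.label_mix not in ("linear_rank", "exponential_rank"):
            raise ValueError(f"unknown label_mix {self.label_mix!r}")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if any(v <= 0 for v in self.edge_values.values()):
            raise ValueError("edge values must be positive")

    def with_(self, **kwargs) -> "CoefficientScheme":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)

    # -- coefficient rules -------------------------------------------------

    def sphere_coefficients(self, rho: int) -> np.ndarray:
        """``b_1 > ... > b_rho > 0`` for a graph of diameter *rho*.

        Index 0 of the returned array is ``b_1``.
        """
        j = np.arange(1, rho + 1)
        if self.sphere_coeffs == "linear":
            return (rho - j + 1).astype(float)
        return np.power(2.0, rho - j)

    def weight(self, label: str) -> float:
        """Label weight ``w(l)``; skeleton sentinels weigh 1."""
        if self.label_weight == "uniform" or not label.isalpha():
            return 1.0
        m = atomic_mass(label)
        if self.label_weight == "mass":
            return m / MASS_U
        return MASS_H / m

    def mix_coefficients(self, alphabet: tuple[str, ...]) -> dict[str, float]:
        """Normalised label coefficients ``c_l`` with ``sum c_l = 1``.

        The alphabet is ranked by ascending atomic mass; symbols without a
        tabulated mass (e.g. the skeleton sentinel) rank last.
        """
        if not alphabet:
            raise ValueError("empty label alphabet")

        def key(lab: str):
            try:
                return (0, atomic_mass(lab), lab)
            except KeyError:
                return (1, 0.0, lab)

        ordered = sorted(set(alphabet), key=key)
        k = len(ordered)
        if self.label_mix == "linear_rank":
            raw = np.array([k - r + 1 for r in range(1, k + 1)], dtype=float)
        else:
            raw = np.power(2.0, -np.arange(1, k + 1, dtype=float))
        raw /= raw.sum()
        return dict(zip(ordered, raw))

    def edge_value(self, label: str) -> float:
        try:
            return self.edge_values[label]
        except KeyError:
            raise KeyError(f"no numeric value defined for edge label {label!r}") from None
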
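"""Thermodynamic identity algebra for binding selectivity analysis.

Free energies in this package are standard binding free energies (ABFEs)
and their pairwise differences:

* RBFE  — relative binding free energy of two ligands on one receptor,
  ``dG_r(R L1 -> R L2) = dG_b(R L2) - dG_b(R L1)``.
* BSFE / RHFE — binding selectivity free energy of one ligand between an
  ordered receptor pair, ``dG_h(RA L -> RB L) = dG_b(RB L) - dG_b(RA L)``;
  the receptor-hopping free energy is its direct alchemical estimate.
* RSFE — receptor swapping free energy for exchanging two ligands across
  two receptors, expressible as a difference of RBFEs or of BSFEs.

All values are in kcal/mol.  Uncertainties follow the reporting convention
of the source calculations: they are *twice* the standard deviation.
Quadrature propagation is scale-invariant, so sums and differences can be
propagated directly on the 2-sigma scale; consumers that need 1-sigma
weights (the network solver) divide by two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "KB_KCAL_MOL_K",
    "Measurement",
    "ThermoContext",
    "InvalidMeasurementError",
    "difference",
    "rhfe_from_abfes",
    "rsfe_from_rbfes",
    "rsfe_from_bsfes",
    "rsfe_from_abfes",
    "SelectivityRatio",
    "selectivity_coefficient",
    "selectivity_ratio_from_rsfe",
    "dg_from_pki",
    "dg_from_kb",
    "kb_from_dg",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872041

LN10 = math.log(10.0)


class InvalidMeasurementError(ValueError):
    """A free-energy value is non-finite or otherwise unusable."""


@dataclass(frozen=True)
class Measurement:
    """A free-energy value with its reported uncertainty.

    Parameters
    ----------
    value : float
        Free energy in kcal/mol.
    uncertainty : float, optional
        Reported as twice the standard deviation (2-sigma), kcal/mol.
        ``None`` for values published without error bars (e.g. experimental
        affinities); absent uncertainties propagate as absent, never as zero.
    """

    value: float
    uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if self.uncertainty is not None and self.uncertainty < 0:
            raise InvalidMeasurementError(
                f"uncertainty must be >= 0, got {self.uncertainty}"
            )

    @property
    def sigma(self) -> Optional[float]:
        """One standard deviation (half the reported 2-sigma)."""
        return None if self.uncertainty is None else self.uncertainty / 2.0

    def __neg__(self) -> "Measurement":
        return Measurement(-self.value, self.uncertainty)

    def __str__(self) -> str:  # pragma: no cover - display helper
        if self.uncertainty is None:
            return f"{self.value:.2f}"
        return f"{self.value:.2f} ± {self.uncertainty:.2f}"


@dataclass(frozen=True)
class ThermoContext:
    """Physical constants and conditions for unit conversions.

    ``temperature`` defaults to 300 K, the simulation temperature of the
    calculations this package analyzes; experimental pKi conversions are
    typically made at 298.15 K, so the temperature is a parameter.
    """

    kB: float = KB_KCAL_MOL_K
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """kB*T in kcal/mol."""
        return self.kB * self.temperature


def _require_finite(*measurements: Measurement) -> None:
    for m in measurements:
        if not math.isfinite(m.value):
            raise InvalidMeasurementError(f"non-finite free energy value: {m.value}")


def difference(final: Measurement, initial: Measurement) -> Measurement:
    """``final - initial`` with quadrature uncertainty propagation.

    The result's uncertainty is ``sqrt(u_f**2 + u_i**2)`` on the 2-sigma
    scale (valid because both inputs are on that scale), or ``None`` if
    either input lacks an uncertainty.
    """
    _require_finite(final, initial)
    if final.uncertainty is None or initial.uncertainty is None:
        u = None
    else:
        u = math.hypot(final.uncertainty, initial.uncertainty)
    return Measurement(final.value - initial.value, u)


def rhfe_from_abfes(abfe_a: Measurement, abfe_b: Measurement) -> Measurement:
    """BSFE for the hop RA -> RB from the two absolute binding free energies.

    ``dG_h(RA L -> RB L) = dG_b(RB L) - dG_b(RA L)``: a negative BSFE means
    the ligand binds receptor B more strongly.
    """
    return difference(abfe_b, abfe_a)


def rsfe_from_rbfes(rbfe_a: Measurement, rbfe_b: Measurement) -> Measurement:
    """Receptor swapping free energy from two RBFEs of the same ligand pair.

    Both RBFEs must be for the same ordered ligand transformation L1 -> L2,
    measured on receptors RA and RB respectively.  The swap starts from
    (L1 bound to RA, L2 bound to RB):

    ``dG_s(RA L1, RB L2) = dG_r(RA; L1->L2) - dG_r(RB; L1->L2)``
    """
    return difference(rbfe_a, rbfe_b)


def rsfe_from_bsfes(bsfe_l1: Measurement, bsfe_l2: Measurement) -> Measurement:
    """Receptor swapping free energy from the two ligands' BSFEs.

    Both BSFEs must be oriented along the same receptor hop RA -> RB:

    ``dG_s(RA L1, RB L2) = dG_h(L1; RA->RB) - dG_h(L2; RA->RB)``
    """
    return difference(bsfe_l1, bsfe_l2)


def rsfe_from_abfes(
    abfe_a_l1: Measurement,
    abfe_a_l2: Measurement,
    abfe_b_l1: Measurement,
    abfe_b_l2: Measurement,
) -> Measurement:
    """Receptor swapping free energy from a complete 2x2 ABFE assignment.

    Equivalent to ``rsfe_from_bsfes`` applied to ABFE-derived BSFEs; kept
    as a convenience for deriving swap values directly from absolute data.
    """
    return rsfe_from_bsfes(
        rhfe_from_abfes(abfe_a_l1, abfe_b_l1),
        rhfe_from_abfes(abfe_a_l2, abfe_b_l2),
    )


@dataclass(frozen=True)
class SelectivityRatio:
    """A dimensionless ratio of binding constants with multiplicative error.

    ``uncertainty_factor`` is the multiplicative 1-sigma factor
    ``exp(sigma_dG / kT)``; the interval is ``value * factor**(+-1)``.
    ``None`` when the source free energy had no uncertainty.
    """

    value: float
    uncertainty_factor: Optional[float] = None


def selectivity_coefficient(
    bsfe: Measurement, ctx: ThermoContext = ThermoContext()
) -> SelectivityRatio:
    """Selectivity coefficient of a ligand for receptor B over receptor A.

    The coefficient is the ratio of binding constants ``Kb(B)/Kb(A)``,
    related to the BSFE of the hop A -> B by

    ``s(L; B over A) = exp(-dG_h(A->B) / kT)``

    so a negative BSFE (stronger binding to B) gives s > 1.
    """
    _require_finite(bsfe)
    s = math.exp(-bsfe.value / ctx.kT)
    factor = None
    if bsfe.uncertainty is not None:
        factor = math.exp(bsfe.sigma / ctx.kT)
    return SelectivityRatio(s, factor)


def selectivity_ratio_from_rsfe(
    rsfe: Measurement, ctx: ThermoContext = ThermoContext()
) -> SelectivityRatio:
    """Ratio of two ligands' selectivity coefficients from a swap free energy.

    For a swap starting from (L1 bound to RA, L2 bound to RB),

    ``s(L1; RA over RB) / s(L2; RA over RB) = exp(+dG_s / kT)``

    A large positive swap free energy means L1 prefers RA (relative to L2)
    much more than L2 does.
    """
    _require_finite(rsfe)
    ratio = math.exp(rsfe.value / ctx.kT)
    factor = None
    if rsfe.uncertainty is not None:
        factor = math.exp(rsfe.sigma / ctx.kT)
    return SelectivityRatio(ratio, factor)


def dg_from_pki(pki: float, ctx: ThermoContext = ThermoContext()) -> Measurement:
    """Standard binding free energy from a pKi, ``dG_b = -kT * pKi * ln 10``.

    Carries no uncertainty (experimental error bars are rarely published
    alongside pKi values).
    """
    if not math.isfinite(pki):
        raise InvalidMeasurementError(f"non-finite pKi: {pki}")
    return Measurement(-ctx.kT * pki * LN10)


def dg_from_kb(kb: float, ctx: ThermoContext = ThermoContext()) -> Measurement:
    """Standard binding free energy from a binding constant, ``-kT ln Kb``."""
    if not (kb > 0):
        raise ValueError(f"binding constant must be > 0, got {kb}")
    return Measurement(-ctx.kT * math.log(kb))


def kb_from_dg(dg: Measurement, ctx: ThermoContext = ThermoContext()) -> float:
    """Binding constant from a standard binding free energy (inverse of
    :func:`dg_from_kb`; round-trips to ~1e-12 relative)."""
    _require_finite(dg)
    return math.exp(-dg.value / ctx.kT)
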
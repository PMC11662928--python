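"""Polymer model mapping lattice occupancy and force to ssDNA extension.

The tethered substrate is an 8.1 knt single strand held at constant
tension.  Its bare extension per nucleotide follows the freely-jointed
chain (FJC), and each bound protein shortens the strand by a fixed
fraction (gamma) of the bare extension of the nucleotides it engages.
Two trimer conformations (compact / de-compact) and the monomeric
construct each carry their own gamma table, interpolated in force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "FJCParams",
    "ExtensionModel",
    "fjc_extension_per_nt",
    "complex_extension",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM_PER_K = 1.380649e-2


@dataclass(frozen=True)
class FJCParams:
    """Freely-jointed-chain parameters for bare ssDNA.

    Parameters
    ----------
    contour_per_nt : float
        Contour length per nucleotide (nm/nt).
    kuhn_length : float
        Kuhn segment length (nm).
    stretch_modulus : float or None
        Enthalpic stretch modulus (pN); ``None`` disables the
        ``1 + F/S`` correction.
    temperature : float
        Absolute temperature (K); experiments run at room temperature.
    """

    contour_per_nt: float = 0.56
    kuhn_length: float = 1.5
    stretch_modulus: Optional[float] = None
    temperature: float = 294.15

    def __post_init__(self) -> None:
        if self.contour_per_nt <= 0:
            raise ValueError("contour_per_nt must be positive")
        if self.kuhn_length <= 0:
            raise ValueError("kuhn_length must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.stretch_modulus is not None and self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be positive or None")

    @property
    def kBT(self) -> float:
        """Thermal energy k_B * T in pN nm."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature


def fjc_extension_per_nt(force, params: FJCParams = FJCParams()):
    """Extension per nucleotide of bare ssDNA at a given tension.

    Evaluates the Langevin-function FJC

    ``x(F) = L_nt * [coth(u) - 1/u] * (1 + F/S)``,  ``u = F*b/(k_B T)``

    where ``L_nt`` is the contour length per nucleotide, ``b`` the Kuhn
    length and the enthalpic term is applied only when a stretch
    modulus ``S`` is configured.

    Parameters
    ----------
    force : float or ndarray
        Tension in pN; must be strictly positive.
    params : FJCParams

    Returns
    -------
    float or ndarray
        Extension per nucleotide (nm/nt), strictly increasing in force
        and bounded by the contour length when the stretch term is off.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be strictly positive")
    u = f * params.kuhn_length / params.kBT
    # coth(u) - 1/u, numerically stable for small and large u
    with np.errstate(over="ignore"):
        langevin = 1.0 / np.tanh(u) - 1.0 / u
    x = params.contour_per_nt * langevin
    if params.stretch_modulus is not None:
        x = x * (1.0 + f / params.stretch_modulus)
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(x)
    return x


def _as_table(table: Mapping[float, float]) -> tuple[np.ndarray, np.ndarray]:
    forces = np.array(sorted(table), dtype=float)
    gammas = np.array([table[f] for f in forces], dtype=float)
    return forces, gammas


@dataclass(frozen=True)
class ExtensionModel:
    """Per-state compaction fractions, tabulated versus force.

    ``gamma_state`` is the fraction by which a bound protein reduces
    the bare FJC extension of the nucleotides in its footprint.  The
    compact trimer compacts most strongly; the de-compacted trimer and
    the monomeric construct compact ~3-fold less, encoding the observed
    ratio of maximal extension reductions.  Values are interpolated
    linearly between tabulated forces and clamped outside the table.
    """

    gamma_compact: Mapping[float, float] = field(
        default_factory=lambda: {10.0: 0.8, 30.0: 0.6, 50.0: 0.3}
    )
    gamma_decompact: Optional[Mapping[float, float]] = None
    gamma_monomer: Optional[Mapping[float, float]] = None

    def __post_init__(self) -> None:
        compact = dict(self.gamma_compact)
        decompact = (
            dict(self.gamma_decompact)
            if self.gamma_decompact is not None
            else {f: g / 3.0 for f, g in compact.items()}
        )
        monomer = (
            dict(self.gamma_monomer)
            if self.gamma_monomer is not None
            else dict(decompact)
        )
        if set(compact) != set(decompact) or set(compact) != set(monomer):
            raise ValueError("gamma tables must share the same force keys")
        for f in compact:
            if not (0.0 <= decompact[f] <= compact[f] <= 1.0):
                raise ValueError(
                    "require 0 <= gamma_decompact <= gamma_compact <= 1 "
                    f"at {f} pN"
                )
            if not (0.0 <= monomer[f] <= 1.0):
                raise ValueError(f"gamma_monomer out of [0, 1] at {f} pN")
        object.__setattr__(self, "gamma_compact", compact)
        object.__setattr__(self, "gamma_decompact", decompact)
        object.__setattr__(self, "gamma_monomer", monomer)

    def gamma(self, state: str, force: float) -> float:
        """Compaction fraction for a site state at the given force."""
        table = {
            "compact": self.gamma_compact,
            "decompact": self.gamma_decompact,
            "monomer": self.gamma_monomer,
        }.get(state)
        if table is None:
            if state == "empty":
                return 0.0
            raise ValueError(f"unknown site state {state!r}")
        forces, gammas = _as_table(table)
        return float(np.interp(force, forces, gammas))


def complex_extension(
    state_counts: Mapping[str, int],
    force: float,
    fjc: FJCParams = FJCParams(),
    ext: ExtensionModel = ExtensionModel(),
    n_nt: int = 8100,
    trimer_footprint: int = 50,
    subunit_footprint: int = 17,
) -> float:
    """End-to-end extension (nm) of the nucleoprotein complex.

    The bare strand contributes ``n_nt * x_fjc(F)``; every occupied
    site subtracts ``gamma_state * footprint * x_fjc(F)``, with trimer
    sites spanning 50 nt and monomer sites 17 nt.  Extension is linear
    in the state counts.
    """
    x = fjc_extension_per_nt(force, fjc)
    known = {"empty", "compact", "decompact", "monomer"}
    unknown = set(state_counts) - known
    if unknown:
        raise ValueError(f"unknown site state(s): {sorted(unknown)}")
    counts = {s: int(state_counts.get(s, 0)) for s in known}
    if any(c < 0 for c in counts.values()):
        raise ValueError("state counts must be non-negative")
    occupied_nt = (
        (counts["compact"] + counts["decompact"]) * trimer_footprint
        + counts["monomer"] * subunit_footprint
    )
    if occupied_nt > n_nt:
        raise ValueError(
            f"occupied footprint {occupied_nt} nt exceeds lattice of {n_nt} nt"
        )
    reduction = (
        counts["compact"] * ext.gamma("compact", force) * trimer_footprint
        + counts["decompact"] * ext.gamma("decompact", force) * trimer_footprint
        + counts["monomer"] * ext.gamma("monomer", force) * subunit_footprint
    ) * x
    return n_nt * x - reduction
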
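"""DNA elasticity: tether-length change per nucleotide at a given load.

In the tweezers geometry the enzyme's progress is read out as a change in
bead-to-bead distance.  Converting nanometers to nucleotides requires the
equilibrium extension per nucleotide of single- or double-stranded DNA at
the applied tension:

* dsDNA — extensible worm-like chain, high-force interpolation:
  ``x/L = 1 - (1/2)*sqrt(kBT/(F*P)) + F/S`` with contour ``L`` = rise per
  base pair.
* ssDNA — inextensible worm-like chain, same entropic interpolation without
  the stretch term, with contour per nucleotide ``L_ss``.

Which spacing applies depends on the replication mode and pulling geometry:
under opposing load, primer extension consumes single-stranded template
(tether shortens by the ss spacing per nucleotide) while strand displacement
shortens by the ds spacing; under aiding load the downstream duplex grows,
so the ds spacing applies in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import KBT_22C, InvalidParameterError

__all__ = [
    "PolymerParams",
    "InvalidLoadError",
    "ConfigurationError",
    "extension_per_nt",
    "nucleotides_from_distance",
    "conversion_strand",
]


class InvalidLoadError(ValueError):
    """Force outside the domain of the elasticity interpolation."""


class ConfigurationError(ValueError):
    """Unknown replication mode / pulling geometry combination."""


@dataclass(frozen=True)
class PolymerParams:
    """Elastic parameters (standard literature values at ~150 mM salt).

    ``ds_persistence`` nm; ``ds_stretch_modulus`` pN; ``ds_rise`` nm/bp;
    ``ss_persistence`` nm; ``ss_contour_per_nt`` nm/nt.
    """

    ds_persistence: float = 50.0
    ds_stretch_modulus: float = 1200.0
    ds_rise: float = 0.34
    ss_persistence: float = 0.75
    ss_contour_per_nt: float = 0.59

    def __post_init__(self) -> None:
        vals = (self.ds_persistence, self.ds_stretch_modulus, self.ds_rise,
                self.ss_persistence, self.ss_contour_per_nt)
        if min(vals) <= 0:
            raise InvalidParameterError("polymer parameters must be positive")
        if self.ds_rise > self.ss_contour_per_nt:
            raise InvalidParameterError(
                "ds rise cannot exceed ss contour per nt")


DEFAULT_POLYMER = PolymerParams()

# Below ~kBT/(4P) the entropic interpolation turns nonphysical for ssDNA;
# clip the contour fraction instead of extrapolating.
_MIN_FRACTION = 1e-6


def extension_per_nt(F, strand: str, params: PolymerParams = DEFAULT_POLYMER,
                     kBT: float = KBT_22C):
    """Equilibrium extension per nucleotide (nm) at force magnitude F (pN).

    ``strand`` is ``"ss"`` or ``"ds"``.  Accepts scalar or array F; valid
    above ~1-2 pN (the interpolation degrades below; F <= 0 raises).
    """
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise InvalidLoadError("force magnitude must be positive")
    if strand == "ds":
        P, L = params.ds_persistence, params.ds_rise
        frac = 1.0 - 0.5 * np.sqrt(kBT / (F * P)) + F / params.ds_stretch_modulus
    elif strand == "ss":
        P, L = params.ss_persistence, params.ss_contour_per_nt
        frac = 1.0 - 0.5 * np.sqrt(kBT / (F * P))
    else:
        raise ConfigurationError(f"unknown strand type {strand!r}")
    out = L * np.clip(frac, _MIN_FRACTION, None)
    return out if out.ndim else float(out)


_SPACING = {
    # (geometry, mode) -> strand whose spacing divides the distance change
    ("opposing", "primer_extension"): "ss",
    ("opposing", "strand_displacement"): "ds",
    ("aiding", "primer_extension"): "ds",
    ("aiding", "strand_displacement"): "ds",
}


def conversion_strand(mode: str, geometry: str) -> str:
    """Strand type whose per-nt spacing converts distance to nucleotides."""
    key = (geometry, mode)
    if key not in _SPACING:
        raise ConfigurationError(
            f"unknown geometry/mode combination {geometry!r}/{mode!r}")
    return _SPACING[key]


def nucleotides_from_distance(trace, mode: str, geometry: str,
                              params: PolymerParams = DEFAULT_POLYMER,
                              kBT: float = KBT_22C) -> np.ndarray:
    """Convert a trace's tether-length change to nucleotides incorporated.

    ``trace`` provides ``delta_x`` (nm, signed: negative = shortening) and
    ``force`` (pN, signed or magnitude; per-sample or constant).  Under
    opposing load the tether shortens as replication proceeds, under aiding
    load it lengthens; the returned count is positive either way.
    """
    key = (geometry, mode)
    if key not in _SPACING:
        raise ConfigurationError(
            f"unknown geometry/mode combination {geometry!r}/{mode!r}")
    delta_x = np.asarray(trace.delta_x, dtype=float)
    force = np.abs(np.asarray(trace.force, dtype=float))
    spacing = extension_per_nt(force, _SPACING[key], params, kBT)
    sign = -1.0 if geometry == "opposing" else 1.0
    return sign * delta_x / spacing
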
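"""Deterministic mass arithmetic for intact histones and their ETD fragments.

All masses derive from a single embedded element table
(``data/masses.json``): monoisotopic masses from the standard nuclide
tables, and IUPAC *conventional* (abridged) atomic weights for the
isotope-averaged scale.  Intact-precursor work defaults to the average
scale — intact-protein deconvolution at the resolutions used for histone
families reports isotope-averaged masses — while fragment matching is
always monoisotopic.

The two shipped backbones are the mature murine histone H4 (102 aa,
initiator Met removed, fixed N-terminal acetylation) and the GluC
middle-down H3.2 tail (residues 1-50, ending at the first Glu).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO

MassScale = Literal["average", "monoisotopic"]

_DATA = json.loads(resources.files("histoquant.data").joinpath("masses.json").read_text())

PROTON_DA: float = _DATA["proton_da"]
_ELEMENTS: dict[str, dict[str, float]] = _DATA["elements"]
_RESIDUES: dict[str, dict[str, int]] = _DATA["residues"]
_PTM_FORMULAS: dict[str, dict[str, int]] = _DATA["ptms"]

VALID_STATES = ("un", "ac", "me1", "me2", "me3")


def composition_mass(formula: Mapping[str, int], scale: MassScale) -> float:
    """Mass of an elemental composition on the requested scale."""
    key = "avg" if scale == "average" else "mono"
    try:
        return sum(_ELEMENTS[el][key] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc.args[0]!r}") from None


def _check_scale(scale: str) -> None:
    if scale not in ("average", "monoisotopic"):
        raise ValueError(f"mass scale must be 'average' or 'monoisotopic', got {scale!r}")


@dataclass(frozen=True)
class PTMDelta:
    """Mass increment of a post-translational modification."""

    name: str
    mono_da: float
    avg_da: float

    def mass(self, scale: MassScale) -> float:
        return self.avg_da if scale == "average" else self.mono_da


PTM_DELTAS: dict[str, PTMDelta] = {
    name: PTMDelta(
        name,
        mono_da=composition_mass(f, "monoisotopic"),
        avg_da=composition_mass(f, "average"),
    )
    for name, f in _PTM_FORMULAS.items()
}


@dataclass(frozen=True)
class BackboneSequence:
    """A histone backbone: sequence plus fixed (non-variable) modifications.

    ``fixed_mods`` holds 1-based ``(position, ptm)`` pairs; position 1 with
    ``"ac"`` encodes N-terminal alpha-amine acetylation.
    """

    name: str
    residues: str
    fixed_mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("backbone sequence must be nonempty")
        bad = set(self.residues) - set(_RESIDUES)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        for pos, ptm in self.fixed_mods:
            if not (1 <= pos <= len(self.residues)):
                raise ValueError(f"fixed-mod position {pos} outside sequence")
            if ptm not in PTM_DELTAS:
                raise ValueError(f"unknown PTM {ptm!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _load_backbones() -> dict[str, BackboneSequence]:
    fixed = {"H4": ((1, "ac"),)}  # N-terminal acetylation is fixed on H4
    out = {}
    with resources.files("histoquant.data").joinpath("backbones.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out[rec.id] = BackboneSequence(rec.id, str(rec.seq), fixed.get(rec.id, ()))
    return out


BACKBONES: dict[str, BackboneSequence] = _load_backbones()


@dataclass(frozen=True)
class MSConfig:
    """Acquisition/search parameters.

    ``ms1_window_da`` is the full MS1 isolation width (peaks match a class
    within +/- half this window); ``frag_tol_ppm`` applies to c/z fragments.
    """

    ms1_window_da: float = 3.4
    frag_tol_ppm: float = 10.0
    proton_da: float = PROTON_DA
    mass_scale: MassScale = "average"
    scan_range_h3: tuple[float, float] = (585.0, 640.0)
    scan_range_h4: tuple[float, float] = (700.0, 1400.0)

    def __post_init__(self) -> None:
        if self.ms1_window_da <= 0 or self.frag_tol_ppm <= 0:
            raise ValueError("window and tolerance must be strictly positive")
        _check_scale(self.mass_scale)
        for lo, hi in (self.scan_range_h3, self.scan_range_h4):
            if not lo < hi:
                raise ValueError("scan range must be well-ordered")

    def scan_range(self, family: str) -> tuple[float, float]:
        return self.scan_range_h3 if family.startswith("H3") else self.scan_range_h4


@dataclass(frozen=True)
class StandardCurve:
    """Linear HPLC peak-area standard curve: ug = (area - intercept)/slope."""

    family: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be nonzero")


H3_CURVE = StandardCurve("H3", slope=14.221, intercept=2.6558)
H4_CURVE = StandardCurve("H4", slope=31.215, intercept=6.0114)


def _residue_masses(residues: str, scale: MassScale) -> np.ndarray:
    key = "avg" if scale == "average" else "mono"
    return np.array(
        [sum(_ELEMENTS[el][key] * n for el, n in _RESIDUES[r].items()) for r in residues]
    )


def _validate_site_states(backbone: BackboneSequence, site_states: Mapping[int, str]) -> None:
    for pos, state in site_states.items():
        if not (1 <= pos <= len(backbone)):
            raise ValueError(f"site {pos} outside {backbone.name} (length {len(backbone)})")
        if state not in VALID_STATES:
            raise ValueError(f"unknown PTM state {state!r} at site {pos}")
        if state != "un" and backbone.residues[pos - 1] != "K":
            raise ValueError(
                f"variable PTM {state} at non-lysine residue "
                f"{backbone.residues[pos - 1]}{pos} of {backbone.name}"
            )


def proteoform_mass(
    backbone: BackboneSequence,
    site_states: Mapping[int, str] | None = None,
    scale: MassScale = "average",
) -> float:
    """Neutral mass of a fully specified proteoform.

    Additive model: backbone mass (residues + H2O + fixed mods) plus the sum
    of variable per-site PTM deltas.  Sites mapped to ``"un"`` contribute
    nothing; variable PTMs are only accepted on lysines.
    """
    _check_scale(scale)
    site_states = site_states or {}
    _validate_site_states(backbone, site_states)
    mass = float(_residue_masses(backbone.residues, scale).sum())
    mass += composition_mass({"H": 2, "O": 1}, scale)  # termini
    for _, ptm in backbone.fixed_mods:
        mass += PTM_DELTAS[ptm].mass(scale)
    for _, state in site_states.items():
        if state != "un":
            mass += PTM_DELTAS[state].mass(scale)
    return mass


def mz_to_neutral(mz: float, z: int, proton_da: float = PROTON_DA) -> float:
    """Neutral mass from an observed m/z and positive charge (proton adducts)."""
    if z < 1:
        raise ValueError("charge must be a positive integer")
    if mz <= proton_da:
        raise ValueError("m/z must exceed the proton mass")
    return (mz - proton_da) * z


def neutral_to_mz(neutral: float, z: int, proton_da: float = PROTON_DA) -> float:
    if z < 1:
        raise ValueError("charge must be a positive integer")
    return neutral / z + proton_da


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed parts-per-million error of an observed vs theoretical mass."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ETD backbone cleavage at N-Calpha: N-terminal c ions (quasi-molecular,
# +NH2 on the amide) and C-terminal z-dot radicals.  With prefix/suffix the
# bare residue sums:  c_i = prefix_i + NH3,  z*_j = suffix_j + H2O - NH3 + H.
# The pair constants live only here; correctness is pinned by the
# complementarity invariant c_i + z_{L-i} = const and the precursor ppm check.
def etd_fragments(
    backbone: BackboneSequence,
    site_states: Mapping[int, str] | None = None,
    scale: MassScale = "monoisotopic",
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral c- and z-ion ladders (each of length L-1) for a proteoform.

    ``c[i]`` covers residues 1..i+1 from the N-terminus; ``z[j]`` covers the
    last j+1 residues.  A PTM at site s shifts exactly the fragments whose
    span includes s.
    """
    _check_scale(scale)
    if len(backbone) < 2:
        raise ValueError("sequence must have length >= 2")
    site_states = site_states or {}
    _validate_site_states(backbone, site_states)

    deltas = np.zeros(len(backbone))
    for pos, ptm in backbone.fixed_mods:
        deltas[pos - 1] += PTM_DELTAS[ptm].mass(scale)
    for pos, state in site_states.items():
        if state != "un":
            deltas[pos - 1] += PTM_DELTAS[state].mass(scale)

    res = _residue_masses(backbone.residues, scale) + deltas
    prefix = np.cumsum(res)[:-1]
    suffix = np.cumsum(res[::-1])[:-1]

    nh3 = composition_mass({"N": 1, "H": 3}, scale)
    h2o = composition_mass({"H": 2, "O": 1}, scale)
    h = composition_mass({"H": 1}, scale)
    c_ions = prefix + nh3
    z_ions = suffix + (h2o - nh3 + h)
    return c_ions, z_ions


def ug_from_peak_area(area: float, curve: StandardCurve) -> float:
    """Convert an HPLC peak area to micrograms via the family standard curve.

    May return a negative value for sub-intercept areas; the caller decides
    how to treat those.
    """
    return (area - curve.intercept) / curve.slope
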
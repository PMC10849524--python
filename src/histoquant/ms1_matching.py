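"""MS1 precursor assignment: charged peaks -> isobaric classes.

Each charged MS1 peak is converted to a neutral mass and matched to the
nearest isobaric class if it lies within half the MS1 window (the window is
the full isolation width).  Intensities for a class are summed across charge
states and scans; peaks outside the family scan range, without charge, or
outside every window are counted but never matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .masscalc import MSConfig, mz_to_neutral
from .proteoform_space import IsobaricClass
from .spectra_io import SpectrumPeakList


@dataclass
class PrecursorObservation:
    class_index: int
    class_mass: float
    neutral_mass: float  # intensity-weighted mean of contributing peaks
    total_intensity: float
    contributing: list[tuple[str, int]] = field(default_factory=list)  # (scan, z)
    ppm_to_representative: float = 0.0


@dataclass
class AssignmentSummary:
    total_intensity: float = 0.0
    matched_intensity: float = 0.0
    unmatched_intensity: float = 0.0
    out_of_range_intensity: float = 0.0
    uncharged_peaks: int = 0
    unmatched_peaks: int = 0
    ties: int = 0


def assign_precursors(
    spectra: Sequence[SpectrumPeakList],
    classes: Sequence[IsobaricClass],
    config: MSConfig,
) -> tuple[list[PrecursorObservation], AssignmentSummary]:
    """Assign charged MS1 peaks to isobaric classes within the MS1 window.

    Ties at identical distance break deterministically to the lower-mass
    class.  Returns per-class observations (classes with no support are
    omitted) plus a conservation summary.
    """
    half_window = config.ms1_window_da / 2.0
    reps = [c.representative_mass for c in classes]
    summary = AssignmentSummary()
    acc: dict[int, dict] = {}

    for spec in spectra:
        if spec.level != "MS1":
            continue
        in_range = None
        if spec.family_hint in ("H3", "H4"):
            in_range = config.scan_range(spec.family_hint)
        for mz, intensity, z in zip(spec.mz, spec.intensity, spec.charge):
            summary.total_intensity += intensity
            if in_range is not None and not (in_range[0] <= mz <= in_range[1]):
                summary.out_of_range_intensity += intensity
                continue
            if z is None:
                summary.uncharged_peaks += 1
                summary.unmatched_intensity += intensity
                continue
            neutral = mz_to_neutral(mz, z, config.proton_da)
            best, best_dist = None, None
            for idx, rep in enumerate(reps):
                dist = abs(neutral - rep)
                if best_dist is None or dist < best_dist - 1e-12:
                    best, best_dist = idx, dist
                elif abs(dist - best_dist) <= 1e-12 and reps[idx] < reps[best]:
                    summary.ties += 1
                    best = idx
            if best is None or best_dist > half_window:
                summary.unmatched_peaks += 1
                summary.unmatched_intensity += intensity
                continue
            summary.matched_intensity += intensity
            slot = acc.setdefault(
                best, {"intensity": 0.0, "wmass": 0.0, "contrib": []}
            )
            slot["intensity"] += intensity
            slot["wmass"] += neutral * intensity
            slot["contrib"].append((spec.scan_id, z))

    observations = []
    for idx in sorted(acc):
        slot = acc[idx]
        mean_mass = slot["wmass"] / slot["intensity"] if slot["intensity"] > 0 else reps[idx]
        observations.append(
            PrecursorObservation(
                class_index=idx,
                class_mass=reps[idx],
                neutral_mass=mean_mass,
                total_intensity=slot["intensity"],
                contributing=slot["contrib"],
                ppm_to_representative=1e6 * (mean_mass - reps[idx]) / reps[idx],
            )
        )
    return observations, summary
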
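"""End-to-end glue: spectra -> precursor classes -> apportioned fractions ->
normalized abundance table."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .aggregation_stats import normalize
from .masscalc import MSConfig, mz_to_neutral
from .ms1_matching import assign_precursors
from .ms2_localization import apportion, match_fragments
from .proteoform_space import (
    IsobaricClass,
    SiteStateSchema,
    enumerate_proteoforms,
    isobaric_classes,
)
from .spectra_io import RunManifest, SpectrumPeakList
from .synthetic_data import GroundTruth, SimulationConfig, simulate_mixture, simulate_spectra


def quantify_run(
    spectra: Sequence[SpectrumPeakList],
    schema: SiteStateSchema,
    config: MSConfig,
    classes: Sequence[IsobaricClass] | None = None,
) -> list[tuple[float, dict]]:
    """Quantify one LC-MS run (MS1 + MS2 spectra of a single family).

    Returns per-class (precursor intensity, {proteoform: fraction}) pairs.
    Classes seen at MS1 but never fragmented fall back to a uniform split
    across members (ambiguous); single-member classes are exact.
    """
    if classes is None:
        classes = isobaric_classes(enumerate_proteoforms(schema), config, schema)
    ms1 = [s for s in spectra if s.level == "MS1"]
    ms2 = [s for s in spectra if s.level == "MS2"]
    observations, _ = assign_precursors(ms1, classes, config)
    intensity_by_class = {o.class_index: o.total_intensity for o in observations}

    fractions_by_class: dict[int, dict] = {}
    for spec in ms2:
        prec_neutral = mz_to_neutral(spec.precursor.mz, spec.precursor.charge, config.proton_da)
        ci = min(
            range(len(classes)),
            key=lambda i: abs(classes[i].representative_mass - prec_neutral),
        )
        if abs(classes[ci].representative_mass - prec_neutral) > config.ms1_window_da / 2:
            continue
        evidence = match_fragments(spec, classes[ci].members, schema, config)
        quant = apportion(evidence)
        prev = fractions_by_class.setdefault(ci, {})
        for p, f in zip(classes[ci].members, quant.fractions):
            prev[p] = prev.get(p, 0.0) + f
    # average fractions over multiple MS2 spectra of the same class
    results = []
    for ci, intensity in sorted(intensity_by_class.items()):
        members = classes[ci].members
        fr = fractions_by_class.get(ci)
        if fr is None:
            fr = {p: 1.0 / len(members) for p in members}
        else:
            total = sum(fr.values())
            fr = {p: v / total for p, v in fr.items() if v > 0}
        results.append((intensity, fr))
    return results


def run_end_to_end(
    schema: SiteStateSchema,
    sim_config: SimulationConfig,
    ms_config: MSConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """simulate -> quantify -> normalize; returns (abundance table, truth)."""
    ms_config = ms_config or MSConfig()
    truth = simulate_mixture(schema, sim_config)
    spectra_by_run, classes = simulate_spectra(truth, schema, ms_config)
    class_quants = {
        key: quantify_run(spectra, schema, ms_config, classes)
        for key, spectra in spectra_by_run.items()
    }
    table = normalize(class_quants, truth.manifest.to_frame(), schema.family)
    return table, truth
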
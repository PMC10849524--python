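"""Fragment matching, NNLS apportionment, and site localization."""

import numpy as np
import pytest

from histoquant.masscalc import MSConfig, PROTON_DA, PTM_DELTAS
from histoquant.ms2_localization import (
    apportion,
    candidate_fragment_masses,
    localize,
    match_fragments,
)
from histoquant.proteoform_space import parse_notation, realize_exact
from histoquant.spectra_io import Precursor, SpectrumPeakList


def pf(notation, schema):
    return realize_exact(parse_notation(notation), schema)


def spectrum_from_fractions(candidates, fractions, schema, scale=1.0, rng=None, cv=0.0,
                            coverage=1.0, subset=None):
    """Simulated ETD spectrum: z=1 peaks at each candidate fragment mass with
    intensity = sum of owning candidates' fractions (linear mixing)."""
    intensity = {}
    for p, x in zip(candidates, fractions):
        frags = candidate_fragment_masses(p, schema)
        if subset is not None:
            frags = frags[subset]
        if coverage < 1.0:
            frags = frags[rng.random(len(frags)) < coverage]
        for m in frags:
            intensity[float(m)] = intensity.get(float(m), 0.0) + x * scale
    masses = sorted(intensity)
    noise = rng.lognormal(-0.5 * np.log(1 + cv**2), np.sqrt(np.log(1 + cv**2)), len(masses)) \
        if cv > 0 else np.ones(len(masses))
    return SpectrumPeakList(
        level="MS2",
        scan_id="ms2",
        mz=[m + PROTON_DA for m in masses],
        intensity=[intensity[m] * n for m, n in zip(masses, noise)],
        charge=[1] * len(masses),
        precursor=Precursor(800.0, 14),
    )


class TestMatchFragments:
    def test_single_candidate_noise_free_all_matched(self, h4_schema, ms_config):
        cand = [pf("H4<K16ac>", h4_schema)]
        spec = spectrum_from_fractions(cand, [1.0], h4_schema)
        ev = match_fragments(spec, cand, h4_schema, ms_config)
        assert ev.residual_masses.size == 0
        assert ev.incidence.shape[1] == 1
        assert np.all(ev.incidence >= 1)

    def test_peak_outside_tolerance_goes_to_residual(self, h4_schema, ms_config):
        cand = [pf("H4<>", h4_schema)]
        frag = candidate_fragment_masses(cand[0], h4_schema)[10]
        off = frag * (1 + 15e-6)  # 15 ppm away
        spec = SpectrumPeakList(
            "MS2", "s", [off + PROTON_DA], [5.0], [1], precursor=Precursor(800.0, 14)
        )
        ev = match_fragments(spec, cand, h4_schema, ms_config)
        assert ev.incidence.shape[0] == 0
        assert ev.residual_masses.size == 1

    def test_positional_isomers_have_discriminating_rows(self, h4_schema, ms_config):
        a = pf("H4<K8acK20me3>", h4_schema)
        b = pf("H4<K16acK20me3>", h4_schema)
        spec = spectrum_from_fractions([a, b], [0.5, 0.5], h4_schema)
        ev = match_fragments(spec, [a, b], h4_schema, ms_config)
        # c8..c15 differ by one acetyl between the isomers -> discriminating rows
        disc = np.abs(ev.incidence[:, 0] - ev.incidence[:, 1]).sum()
        assert disc > 0
        ca = candidate_fragment_masses(a, h4_schema)[:101]
        cb = candidate_fragment_masses(b, h4_schema)[:101]
        shifted = np.flatnonzero(np.abs(ca - cb) > 1e-6)
        assert shifted.min() == 7 and shifted.max() == 14  # c8..c15 (0-based)
        assert np.allclose(np.abs(ca - cb)[shifted], PTM_DELTAS["ac"].mono_da)

    def test_empty_candidates_rejected(self, h4_schema, ms_config):
        spec = SpectrumPeakList("MS2", "s", [500.0], [1.0], [1], precursor=Precursor(800.0, 14))
        with pytest.raises(ValueError):
            match_fragments(spec, [], h4_schema, ms_config)


class TestApportion:
    def test_single_candidate_fraction_one(self, h4_schema, ms_config):
        cand = [pf("H4<K16ac>", h4_schema)]
        ev = match_fragments(spectrum_from_fractions(cand, [1.0], h4_schema), cand,
                             h4_schema, ms_config)
        q = apportion(ev)
        assert q.fractions == pytest.approx([1.0])
        assert not q.ambiguous

    def test_noise_free_70_30_mixture(self, h4_schema, ms_config):
        cands = [pf("H4<K8acK20me3>", h4_schema), pf("H4<K16acK20me3>", h4_schema)]
        spec = spectrum_from_fractions(cands, [0.7, 0.3], h4_schema)
        ev = match_fragments(spec, cands, h4_schema, ms_config)
        q = apportion(ev)
        # independent linear-algebra oracle: unconstrained least squares on A, b
        oracle, *_ = np.linalg.lstsq(ev.incidence, ev.intensities, rcond=None)
        oracle /= oracle.sum()
        assert q.fractions == pytest.approx([0.7, 0.3], abs=1e-6)
        assert q.fractions == pytest.approx(oracle, abs=1e-9)

    def test_indistinguishable_candidates_split_uniformly(self, h4_schema, ms_config):
        # same composition -> identical masses -> zero discriminating fragments
        cands = [pf("H4<K8acK20me3>", h4_schema), pf("H4<K16acK20me3>", h4_schema)]
        shared = np.flatnonzero(
            np.abs(candidate_fragment_masses(cands[0], h4_schema)
                   - candidate_fragment_masses(cands[1], h4_schema)) < 1e-9
        )
        spec = spectrum_from_fractions(cands, [0.7, 0.3], h4_schema, subset=shared)
        ev = match_fragments(spec, cands, h4_schema, ms_config)
        q = apportion(ev)
        assert q.fractions == pytest.approx([0.5, 0.5])
        assert q.ambiguous

    def test_zero_intensity_uniform_with_flag(self, h4_schema, ms_config):
        cands = [pf("H4<K8ac>", h4_schema), pf("H4<K16ac>", h4_schema)]
        spec = spectrum_from_fractions(cands, [0.5, 0.5], h4_schema, scale=0.0)
        ev = match_fragments(spec, cands, h4_schema, ms_config)
        q = apportion(ev)
        assert q.fractions == pytest.approx([0.5, 0.5])
        assert q.ambiguous

    def test_scale_invariance(self, h4_schema, ms_config):
        cands = [pf("H4<K8acK20me3>", h4_schema), pf("H4<K16acK20me3>", h4_schema)]
        spec = spectrum_from_fractions(cands, [0.6, 0.4], h4_schema)
        ev = match_fragments(spec, cands, h4_schema, ms_config)
        base = apportion(ev).fractions
        for k in (1e-3, 7.0, 1e4):
            ev_k = match_fragments(
                spectrum_from_fractions(cands, [0.6, 0.4], h4_schema, scale=k),
                cands, h4_schema, ms_config,
            )
            assert apportion(ev_k).fractions == pytest.approx(base, abs=1e-9)

    def test_candidate_permutation_equivariance(self, h4_schema, ms_config):
        cands = [
            pf("H4<K8acK20me3>", h4_schema),
            pf("H4<K16acK20me3>", h4_schema),
            pf("H4<K5acK20me3>", h4_schema),
        ]
        x = [0.5, 0.3, 0.2]
        spec = spectrum_from_fractions(cands, x, h4_schema)
        f1 = apportion(match_fragments(spec, cands, h4_schema, ms_config)).fractions
        perm = [2, 0, 1]
        f2 = apportion(
            match_fragments(spec, [cands[i] for i in perm], h4_schema, ms_config)
        ).fractions
        assert f2 == pytest.approx(f1[perm], abs=1e-9)

    def test_noisy_recovery_small_batch(self, h4_schema, ms_config):
        rng = np.random.default_rng(21)
        cands = [pf("H4<K8acK20me3>", h4_schema), pf("H4<K16acK20me3>", h4_schema)]
        errs = []
        for _ in range(20):
            x = rng.dirichlet([2.0, 2.0])
            spec = spectrum_from_fractions(cands, x, h4_schema, rng=rng, cv=0.1)
            q = apportion(match_fragments(spec, cands, h4_schema, ms_config))
            errs.append(np.abs(q.fractions - x).mean())
        assert np.mean(errs) <= 0.02


class TestLocalize:
    def test_full_ladder_unambiguous(self, h4_schema, ms_config, h4_classes):
        cand = pf("H4<K12acK16acK31ac>", h4_schema)
        cls = next(c for c in h4_classes if cand in c.members)
        spec = spectrum_from_fractions([cand], [1.0], h4_schema)
        ev = match_fragments(spec, cls.members, h4_schema, ms_config)
        status = localize(ev, cand)
        for site in (12, 16, 31):
            assert status[site] == "unambiguous"

    def test_short_ladder_ambiguous(self, h4_schema, ms_config):
        a = pf("H4<K12ac>", h4_schema)
        b = pf("H4<K16ac>", h4_schema)
        spec = spectrum_from_fractions([a], [1.0], h4_schema, subset=np.arange(4))  # c1..c4
        ev = match_fragments(spec, [a, b], h4_schema, ms_config)
        status = localize(ev, a)
        assert status[12] == "ambiguous"
        assert status[16] == "ambiguous"

    def test_empty_matched_set_all_ambiguous(self, h4_schema, ms_config):
        a = pf("H4<K12ac>", h4_schema)
        spec = SpectrumPeakList("MS2", "s", [123.456], [1.0], [1],
                                precursor=Precursor(800.0, 14))
        ev = match_fragments(spec, [a], h4_schema, ms_config)
        status = localize(ev, a)
        assert set(status.values()) == {"ambiguous"}
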
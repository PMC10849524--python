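"""Fragment matching, mixture apportionment, and PTM-site localization.

Co-isolated isobaric proteoforms fragment together, so an ETD MS2 spectrum
is modeled as a linear mixture of the candidates' c/z ladders.  Observed
fragment masses (10 ppm tolerance) define a fragment-count incidence
matrix A over candidates; precursor intensity is apportioned by
non-negative least squares on A x = b.  Candidate subsets with no discriminating fragments
share their pooled fraction uniformly and raise an ambiguity flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .masscalc import MSConfig, etd_fragments, mz_to_neutral
from .proteoform_space import Proteoform, SiteStateSchema
from .spectra_io import SpectrumPeakList


@dataclass
class FragmentEvidence:
    candidates: tuple[Proteoform, ...]
    # (n_observed, n_candidates); entry = number of the candidate's c/z
    # fragments within tolerance of the observed mass.  Counting (rather
    # than a 0/1 flag) keeps the linear model exact when two fragments of
    # one candidate coincide within the merge radius.
    incidence: np.ndarray
    intensities: np.ndarray  # observed intensity per merged fragment mass
    observed_masses: np.ndarray
    residual_masses: np.ndarray  # observed masses matching no candidate
    residual_intensities: np.ndarray
    frag_tol_ppm: float


@dataclass
class ApportionedQuant:
    fractions: np.ndarray  # per candidate, >= 0, sums to 1 given any support
    residual_norm: float
    ambiguous: bool
    ambiguous_groups: list[tuple[int, ...]] = field(default_factory=list)


def _merge_observed(masses: np.ndarray, intensities: np.ndarray, tol_ppm: float):
    """Merge observed fragment masses within tolerance.

    Greedy chain merge on the sorted masses; the merged mass is the
    intensity-weighted mean (ties toward lower mass via sort stability).
    """
    order = np.argsort(masses, kind="stable")
    merged_m, merged_i = [], []
    for idx in order:
        m, i = masses[idx], intensities[idx]
        if merged_m and abs(m - merged_m[-1]) / merged_m[-1] * 1e6 <= tol_ppm:
            tot = merged_i[-1] + i
            merged_m[-1] = (merged_m[-1] * merged_i[-1] + m * i) / tot if tot > 0 else merged_m[-1]
            merged_i[-1] = tot
        else:
            merged_m.append(float(m))
            merged_i.append(float(i))
    return np.array(merged_m), np.array(merged_i)


def candidate_fragment_masses(p: Proteoform, schema: SiteStateSchema) -> np.ndarray:
    c, z = etd_fragments(schema.backbone_seq(), dict(p.states), "monoisotopic")
    return np.concatenate([c, z])


def match_fragments(
    ms2: SpectrumPeakList,
    candidates: Sequence[Proteoform],
    schema: SiteStateSchema,
    config: MSConfig,
) -> FragmentEvidence:
    """Match observed MS2 peaks to candidate c/z ladders at the ppm tolerance.

    Peaks without charge annotation are neutralized at z=1.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    theo = [candidate_fragment_masses(p, schema) for p in candidates]

    observed = np.array(
        [mz_to_neutral(mz, z or 1, config.proton_da) for mz, z in zip(ms2.mz, ms2.charge)]
    )
    intens = np.asarray(ms2.intensity, dtype=float)
    if observed.size:
        observed, intens = _merge_observed(observed, intens, config.frag_tol_ppm)

    rows, kept_m, kept_i, res_m, res_i = [], [], [], [], []
    for m, i in zip(observed, intens):
        hit = np.array(
            [np.sum(np.abs(t - m) / m * 1e6 <= config.frag_tol_ppm) for t in theo],
            dtype=float,
        )
        if hit.any():
            rows.append(hit)
            kept_m.append(m)
            kept_i.append(i)
        else:
            res_m.append(m)
            res_i.append(i)
    incidence = np.array(rows) if rows else np.zeros((0, len(candidates)))
    return FragmentEvidence(
        candidates=tuple(candidates),
        incidence=incidence,
        intensities=np.array(kept_i),
        observed_masses=np.array(kept_m),
        residual_masses=np.array(res_m),
        residual_intensities=np.array(res_i),
        frag_tol_ppm=config.frag_tol_ppm,
    )


def _indistinguishable_groups(incidence: np.ndarray) -> list[list[int]]:
    """Group candidate columns that are identical (no discriminating rows)."""
    n = incidence.shape[1]
    groups: dict[bytes, list[int]] = {}
    for j in range(n):
        key = incidence[:, j].astype(np.int8).tobytes()
        groups.setdefault(key, []).append(j)
    return list(groups.values())


def apportion(evidence: FragmentEvidence) -> ApportionedQuant:
    """Apportion precursor intensity among candidates by NNLS on A x = b.

    Indistinguishable candidates (identical incidence columns) are collapsed
    before the solve and their pooled fraction split uniformly afterwards;
    scale-invariant in b.
    """
    n = len(evidence.candidates)
    A, b = evidence.incidence, evidence.intensities

    def uniform() -> ApportionedQuant:
        return ApportionedQuant(
            fractions=np.full(n, 1.0 / n),
            residual_norm=float(np.linalg.norm(b)) if b.size else 0.0,
            ambiguous=True,
            ambiguous_groups=[tuple(range(n))] if n > 1 else [],
        )

    if A.shape[0] == 0 or not np.any(b > 0):
        return uniform()

    groups = _indistinguishable_groups(A)
    reps = [g[0] for g in groups]
    A_red = A[:, reps]
    x_red, rnorm = nnls(A_red, b)

    fractions = np.zeros(n)
    for g, xg in zip(groups, x_red):
        for j in g:
            fractions[j] = xg / len(g)
    total = fractions.sum()
    if total <= 0:
        return uniform()
    fractions /= total

    ambiguous_groups = [tuple(g) for g in groups if len(g) > 1 and fractions[g[0]] > 0]
    return ApportionedQuant(
        fractions=fractions,
        residual_norm=float(rnorm),
        ambiguous=bool(ambiguous_groups),
        ambiguous_groups=ambiguous_groups,
    )


def localize(evidence: FragmentEvidence, candidate: Proteoform) -> dict[int, str]:
    """Per-site localization status for one candidate of the class.

    A site is "unambiguous" when the matched fragments exclude every other
    candidate that differs there: some observed fragment is explained by
    this candidate but not by the alternative.  With no matched fragments
    every site is ambiguous.
    """
    try:
        j = evidence.candidates.index(candidate)
    except ValueError:
        raise ValueError("candidate not in evidence") from None
    col = evidence.incidence[:, j] if evidence.incidence.size else np.zeros(0)
    matched_rows = np.flatnonzero(col > 0)
    status: dict[int, str] = {}
    for pos, state in candidate.states:
        if matched_rows.size == 0:
            status[pos] = "ambiguous"
            continue
        rivals = [
            k
            for k, other in enumerate(evidence.candidates)
            if k != j and other.state_at(pos) != state
        ]
        excluded = all(
            np.any(evidence.incidence[matched_rows, k] == 0) for k in rivals
        )
        status[pos] = "unambiguous" if excluded else "ambiguous"
    return status
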
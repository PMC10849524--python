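"""Seeded generators for every input the pipeline consumes.

Three families of fixtures: (1) ground-truth proteoform mixtures and the
MS1/ETD-MS2 spectra they imply, with a discretized-Gaussian charge envelope,
lognormal multiplicative intensity noise, and partial fragment-ladder
coverage; (2) consensome score tables with one node whose HCTs are planted
into the query gene set; (3) differential-methylation / expression tables
with planted inverse promoter associations.  Everything is bit-reproducible
from (seed, config).

Default study design mirrors the emulated experiment: 2 tissues x 3 housing
conditions (TN/RT/SC) x 4 animals, 2 technical replicates each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masscalc import MSConfig, PROTON_DA, neutral_to_mz
from .proteoform_space import (
    ContainsQuery,
    IsobaricClass,
    Proteoform,
    SiteStateSchema,
    enumerate_proteoforms,
    isobaric_classes,
    parse_notation,
    proteoform_neutral_mass,
)
from .ms2_localization import candidate_fragment_masses
from .spectra_io import Precursor, RunManifest, SpectrumPeakList

# per-family charge envelopes chosen so envelope peaks land inside the
# configured scan ranges (H3 tail ~5.3 kDa at 585-640 m/z -> z 8-10;
# H4 ~11.3 kDa at 700-1400 m/z -> z 9-16)
CHARGE_ENVELOPES = {"H3.2": (9.0, 0.8, (8, 10)), "H4": (12.5, 1.8, (9, 16))}

BASE_INTENSITY = 1.0e6


@dataclass(frozen=True)
class PlantedEffect:
    """A percentage-point shift on a {}-metric in one tissue/condition."""

    query: str
    tissue: str
    condition: str
    pp_shift: float


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    family: str = "H4"
    n_proteoforms_active: int = 20
    dirichlet_concentration: float = 1.0
    sample_concentration: float = 2000.0  # Dirichlet kappa for animal-to-animal scatter
    noise_cv: float = 0.1
    fragment_coverage: float = 0.8
    tissues: tuple[str, ...] = ("BAT", "liver")
    conditions: tuple[str, ...] = ("TN", "RT", "SC")
    biological_n: int = 4
    technical_replicates: int = 2
    effect: PlantedEffect | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if not 0 < self.fragment_coverage <= 1:
            raise ValueError("fragment coverage must be in (0, 1]")
        if self.technical_replicates < 1 or self.biological_n < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass
class GroundTruth:
    """Per-sample true abundances plus the manifest describing the design."""

    table: pd.DataFrame  # family, proteoform, sample, condition, tissue, abundance_percent
    manifest: RunManifest
    active: tuple[Proteoform, ...]
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_mixture(schema: SiteStateSchema, config: SimulationConfig) -> GroundTruth:
    """Draw a sparse ground-truth mixture and per-sample abundance table.

    A Dirichlet baseline over the active proteoforms defines the tissue
    profile; each animal's profile is a concentrated Dirichlet draw around
    it, so group means sit near the baseline.  A planted effect moves the
    stated pp mass onto the proteoforms matching its {}-query in one
    (tissue, condition) group before the per-animal draws.
    """
    space = enumerate_proteoforms(schema)
    if config.n_proteoforms_active > len(space):
        raise ValueError("more active proteoforms requested than the space holds")
    rng = _rng(config, 0)
    idx = rng.choice(len(space), size=config.n_proteoforms_active, replace=False)
    active = tuple(space[i] for i in sorted(idx))
    baseline = rng.dirichlet(np.full(len(active), config.dirichlet_concentration))

    effect_mask = None
    if config.effect is not None:
        q = parse_notation(config.effect.query)
        effect_mask = np.array([q.matches(p) for p in active])
        if not effect_mask.any():
            raise ValueError("planted effect query matches no active proteoform")

    rows = []
    manifest_rows = []
    for tissue in config.tissues:
        for condition in config.conditions:
            profile = baseline.copy()
            if (
                config.effect is not None
                and tissue == config.effect.tissue
                and condition == config.effect.condition
            ):
                shift = config.effect.pp_shift / 100.0
                profile = profile.copy()
                profile[effect_mask] += shift * profile[effect_mask] / profile[effect_mask].sum()
                profile[~effect_mask] -= shift * profile[~effect_mask] / profile[~effect_mask].sum()
                if (profile < 0).any():
                    raise ValueError("planted shift exceeds available abundance mass")
            for animal in range(1, config.biological_n + 1):
                sample = f"{tissue}_{condition}_{animal}"
                draw = rng.dirichlet(profile * config.sample_concentration)
                for p, frac in zip(active, draw):
                    rows.append(
                        (schema.family, p.notation(), sample, condition, tissue, 100.0 * frac)
                    )
                for rep in range(1, config.technical_replicates + 1):
                    manifest_rows.append(
                        {
                            "sample": sample,
                            "tissue": tissue,
                            "condition": condition,
                            "replicate": rep,
                        }
                    )
    table = pd.DataFrame(
        rows,
        columns=["family", "proteoform", "sample", "condition", "tissue", "abundance_percent"],
    )
    return GroundTruth(table, RunManifest(tuple(manifest_rows)), active, config)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _charge_weights(family: str) -> tuple[np.ndarray, np.ndarray]:
    center, spread, (zlo, zhi) = CHARGE_ENVELOPES[family]
    zs = np.arange(zlo, zhi + 1)
    w = np.exp(-0.5 * ((zs - center) / spread) ** 2)
    return zs, w / w.sum()


def simulate_spectra(
    truth: GroundTruth,
    schema: SiteStateSchema,
    ms_config: MSConfig | None = None,
) -> tuple[dict[tuple[str, int], list[SpectrumPeakList]], list[IsobaricClass]]:
    """Emit MS1 + per-class ETD MS2 spectra for every (sample, replicate).

    MS1 peaks sit at the charge-envelope m/z of each active proteoform's
    isotope-averaged mass (clipped to the family scan range), intensity
    proportional to abundance x envelope weight.  Each isobaric class with
    active members gets one MS2 spectrum whose z=1 fragment peaks are the
    member-fraction-weighted sum of monoisotopic c/z ladders under a
    Bernoulli coverage mask, scaled by lognormal noise.
    """
    config = truth.config
    ms_config = ms_config or MSConfig()
    rng = _rng(config, 1)
    family_hint = "H3" if schema.family.startswith("H3") else "H4"
    scan_range = ms_config.scan_range(family_hint)
    zs, zw = _charge_weights(schema.family)

    space = enumerate_proteoforms(schema)
    classes = isobaric_classes(space, ms_config, schema)
    class_of = {p: ci for ci, cl in enumerate(classes) for p in cl.members}
    frag_cache = {p: candidate_fragment_masses(p, schema) for p in truth.active}
    avg_mass = {p: proteoform_neutral_mass(p, schema, ms_config.mass_scale) for p in truth.active}

    notation_to_p = {p.notation(): p for p in truth.active}
    out: dict[tuple[str, int], list[SpectrumPeakList]] = {}
    for sample, sub in truth.table.groupby("sample", sort=True):
        abundance = {notation_to_p[n]: a for n, a in zip(sub["proteoform"], sub["abundance_percent"])}
        for rep in range(1, config.technical_replicates + 1):
            spectra: list[SpectrumPeakList] = []
            mzs, intens, charges = [], [], []
            for p, ab in abundance.items():
                noise = _lognormal_noise(rng, config.noise_cv, len(zs))
                for z, w, nz in zip(zs, zw, noise):
                    mz = neutral_to_mz(avg_mass[p], int(z), ms_config.proton_da)
                    if not scan_range[0] <= mz <= scan_range[1]:
                        continue
                    mzs.append(mz)
                    intens.append(BASE_INTENSITY * ab / 100.0 * w * nz)
                    charges.append(int(z))
            order = np.argsort(mzs, kind="stable")
            spectra.append(
                SpectrumPeakList(
                    level="MS1",
                    scan_id=f"{sample}_r{rep}_ms1",
                    mz=[mzs[i] for i in order],
                    intensity=[intens[i] for i in order],
                    charge=[charges[i] for i in order],
                    family_hint=family_hint,
                )
            )
            by_class: dict[int, list[Proteoform]] = {}
            for p in abundance:
                by_class.setdefault(class_of[p], []).append(p)
            for ci in sorted(by_class):
                members = by_class[ci]
                class_ab = sum(abundance[p] for p in members)
                frag_int: dict[float, float] = {}
                for p in members:
                    frac = abundance[p] / class_ab if class_ab > 0 else 0.0
                    frags = frag_cache[p]
                    mask = rng.random(len(frags)) < config.fragment_coverage
                    for fm in frags[mask]:
                        frag_int[float(fm)] = frag_int.get(float(fm), 0.0) + frac
                if not frag_int:
                    continue
                masses = sorted(frag_int)
                noise = _lognormal_noise(rng, config.noise_cv, len(masses))
                rep_mass = classes[ci].representative_mass
                z0 = int(zs[np.argmax(zw)])
                spectra.append(
                    SpectrumPeakList(
                        level="MS2",
                        scan_id=f"{sample}_r{rep}_ms2_c{ci}",
                        mz=[m + ms_config.proton_da for m in masses],
                        intensity=[
                            frag_int[m] * BASE_INTENSITY * class_ab / 100.0 * nz
                            for m, nz in zip(masses, noise)
                        ],
                        charge=[1] * len(masses),
                        precursor=Precursor(
                            mz=neutral_to_mz(rep_mass, z0, ms_config.proton_da),
                            charge=z0,
                            isolation_window_da=ms_config.ms1_window_da,
                        ),
                        family_hint=family_hint,
                    )
                )
            out[(sample, rep)] = spectra
    return out, classes


# ---------------------------------------------------------------------------
# Consensome / enrichment fixtures


def simulate_consensomes(
    n_nodes: int = 50,
    n_genes: int = 1000,
    planted_node: str = "node00",
    overlap_rate: float = 0.8,
    gene_set_size: int = 100,
    n_datasets: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Score tables for ``n_nodes`` consensomes plus a query gene set.

    The query draws ``overlap_rate`` of its genes from the planted node's
    top-5% (HCT) genes and the rest uniformly from outside them; other
    nodes' scores are independent noise, so only the planted node should
    show a footprint.  Returns (scores, gene_set, universe).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 100]))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    node_names = sorted({planted_node} | {f"node{i:02d}" for i in range(n_nodes)})[:n_nodes]
    frames = []
    for node in node_names:
        for d in range(n_datasets):
            frames.append(
                pd.DataFrame(
                    {
                        "node": node,
                        "dataset": f"{node}_ds{d}",
                        "gene": genes,
                        "score": rng.exponential(scale=100.0, size=n_genes),
                    }
                )
            )
    scores = pd.concat(frames, ignore_index=True)

    planted = scores[scores["node"] == planted_node]
    mean_scores = planted.groupby("gene")["score"].mean().sort_values(ascending=False)
    n_hct = max(1, int(n_genes * 0.05))
    hct = list(mean_scores.index[:n_hct])
    n_in = int(round(overlap_rate * gene_set_size))
    picked_in = list(rng.choice(hct, size=min(n_in, len(hct)), replace=False))
    outside = [g for g in genes if g not in set(hct)]
    picked_out = list(rng.choice(outside, size=gene_set_size - len(picked_in), replace=False))
    gene_set = picked_in + picked_out
    return scores, gene_set, genes


# ---------------------------------------------------------------------------
# Methylation / expression fixtures


def simulate_methexpr(
    n_genes: int = 500,
    planted_inverse_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DM and DEG tables with planted inverse promoter associations.

    A ``planted_inverse_fraction`` of genes get strong inverse signal, half
    hypo-up and half hyper-down; the rest are nulls that deterministically
    fail at least one filter.  Returns (dm, deg, truth) where truth maps
    gene -> planted class ("hypo-up", "hyper-down", or "null").
    """
    if not 0 <= planted_inverse_fraction <= 1:
        raise ValueError("planted fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 200]))
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    n_planted = int(round(planted_inverse_fraction * n_genes))
    n_hypo = n_planted // 2 + n_planted % 2
    labels = ["hypo-up"] * n_hypo + ["hyper-down"] * (n_planted - n_hypo)
    labels += ["null"] * (n_genes - n_planted)

    dm_rows, deg_rows, truth_rows = [], [], []
    for gene, label in zip(genes, labels):
        if label == "hypo-up":
            md = -rng.uniform(6.0, 35.0)
            q = 10.0 ** -rng.uniform(6, 30)
            lfc = rng.uniform(0.3, 1.5)
            padj = 10.0 ** -rng.uniform(3, 20)
        elif label == "hyper-down":
            md = rng.uniform(6.0, 35.0)
            q = 10.0 ** -rng.uniform(6, 30)
            lfc = -rng.uniform(0.3, 1.5)
            padj = 10.0 ** -rng.uniform(3, 20)
        else:
            # nulls fail the methylation magnitude filter and the DEG fold filter
            md = rng.uniform(-4.5, 4.5)
            q = rng.uniform(0.0, 1.0)
            lfc = rng.uniform(-0.2, 0.2)
            padj = rng.uniform(0.0, 1.0)
        dm_rows.append((gene, "promoter", md, q))
        deg_rows.append((gene, lfc, padj))
        truth_rows.append((gene, label))
    dm = pd.DataFrame(dm_rows, columns=["gene", "region", "meth_diff", "q"])
    deg = pd.DataFrame(deg_rows, columns=["gene", "log2fc", "padj"])
    truth = pd.DataFrame(truth_rows, columns=["gene", "planted"])
    return dm, deg, truth
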
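"""Seeded generators for every analysis stage of the pipeline.

Each generator emulates the statistical structure one analyzer assumes —
idealized helical/strand backbones, homologs differing by localized torsion
perturbations, coordinate ensembles with per-residue Gaussian noise, two-state
sigmoidal melt curves, and logistic depolymerization time courses — so the
whole pipeline is testable without downloading deposited structures or
instrument exports. All randomness flows through an explicit seed; the same
config always yields byte-identical outputs.

Defaults mirror the study conditions the analyzers target: melt scans over
25-99 degC, a bioreactor charge of 3.75 g PET in 0.150 L, a depolymerization
plateau of 94.1 % with 50 % conversion near 4 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from petprofiler.assay_analytics import (
    MeltCurve,
    PET_REPEAT_UNIT_MASS,
    ProductTimeCourse,
)
from petprofiler.geometry import (
    BackboneGeometryParams,
    backbone_torsions,
    build_backbone,
    wrap_angle,
)
from petprofiler.structure_io import Structure

__all__ = [
    "GeneratorConfig", "CANONICAL_TORSIONS", "make_ideal_structure",
    "perturb_torsions", "make_ensemble", "simulate_melt_curve",
    "simulate_depolymerization",
]

#: canonical (phi, psi) by secondary-structure kind; omega is trans (180)
CANONICAL_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


@dataclass
class GeneratorConfig:
    """Seed and geometry parameters shared by the structure generators."""

    seed: int = 0
    params: BackboneGeometryParams = field(default_factory=BackboneGeometryParams)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one named stream of this config."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def make_ideal_structure(
    n: int,
    kind: str = "helix",
    cfg: GeneratorConfig | None = None,
) -> Structure:
    """An n-residue single-chain backbone with canonical torsions."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    if kind not in CANONICAL_TORSIONS:
        raise ValueError(f"unknown kind {kind!r}; use 'helix' or 'strand'")
    cfg = cfg or GeneratorConfig()
    phi, psi = CANONICAL_TORSIONS[kind]
    torsions = [(phi, psi, 180.0)] * n
    return build_backbone(torsions, cfg.params, structure_id=f"ideal-{kind}-{n}")


def perturb_torsions(
    s: Structure,
    residues: Sequence[int],
    sigma: float,
    cfg: GeneratorConfig | None = None,
    chain_id: str | None = None,
    perturb_omega: bool = False,
) -> Structure:
    """Rebuild a backbone with Gaussian torsion offsets at named residues.

    ``residues`` are author numbers. Offsets (SD ``sigma`` degrees) are added
    to phi and psi (and omega when requested) of exactly those residues, then
    the chain is rebuilt from its torsion list — so the perturbation is local
    in torsion space by construction, the synthetic analogue of a homolog
    whose loops diverge while the rest of the fold is conserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    cfg = cfg or GeneratorConfig()
    chain_id = chain_id or s.first_chain_id()
    chain = s.chain(chain_id)
    known = {r.author_number for r in chain}
    missing = set(residues) - known
    if missing:
        raise ValueError(f"residues not in chain {chain_id!r}: {sorted(missing)}")

    profile = backbone_torsions(s, chain_id)
    rng = cfg.rng(stream=1)
    target = set(residues)
    torsions: list[tuple[float | None, float | None, float | None]] = []
    for entry in profile:
        phi, psi, omega = entry.phi, entry.psi, entry.omega
        if entry.key[0] in target:
            if phi is not None:
                phi = wrap_angle(phi + sigma * rng.standard_normal())
            if psi is not None:
                psi = wrap_angle(psi + sigma * rng.standard_normal())
            if perturb_omega and omega is not None:
                omega = wrap_angle(omega + sigma * rng.standard_normal())
        torsions.append((phi, psi, omega))
    first = chain[0].author_number
    return build_backbone(
        torsions, cfg.params, chain_id=chain_id,
        structure_id=f"{s.id}-perturbed", first_residue_number=first,
    )


def make_ensemble(
    s: Structure,
    sigma_profile: Sequence[float] | float,
    n_frames: int,
    cfg: GeneratorConfig | None = None,
    chain_id: str | None = None,
) -> np.ndarray:
    """Gaussian-noise coordinate ensemble around a reference Ca trace.

    Returns (n_frames, n_res, 3): each frame is the reference CA coordinates
    plus independent isotropic Gaussian noise with per-residue SD from
    ``sigma_profile`` (scalar or per-residue, Angstrom per coordinate). Noise
    is frame-independent — a deliberately memoryless stand-in for a
    molecular-dynamics trajectory, sufficient to exercise the RMSF stage.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    cfg = cfg or GeneratorConfig()
    chain_id = chain_id or s.first_chain_id()
    ref = s.ca_coords(chain_id)
    n_res = ref.shape[0]
    sigma = np.broadcast_to(np.asarray(sigma_profile, dtype=float), (n_res,))
    if np.any(sigma < 0):
        raise ValueError("sigma_profile must be nonnegative")
    rng = cfg.rng(stream=2)
    noise = rng.standard_normal((n_frames, n_res, 3)) * sigma[None, :, None]
    return ref[None, :, :] + noise


def simulate_melt_curve(
    tm: float,
    slope: float = 1.0,
    amplitude: float = 1.0,
    baseline_pre: float = 0.05,
    baseline_post: float = 0.25,
    drift_pre: float = 0.0,
    drift_post: float = 0.0,
    noise_sd: float = 0.0,
    grid: tuple[float, float, float] = (25.0, 99.0, 0.5),
    cfg: GeneratorConfig | None = None,
) -> MeltCurve:
    """Two-state sigmoidal thermal-shift curve with linear baselines.

    signal(T) = pre(T) + (post(T) - pre(T) + amplitude) * logistic((T - tm)/slope),
    plus Gaussian noise; pre/post are the folded/unfolded baselines with
    optional linear drifts. The logistic inflection sits exactly at ``tm``,
    so the analyzer's first-derivative maximum is the generating parameter.
    The default logistic scale of 1.0 degC gives a 10-90% transition width of
    ~4.4 degC, typical of a cooperative two-state melt of a small globular
    protein watched by a hydrophobic dye. Default grid spans 25-99 degC in
    0.5 degC steps, the usual real-time-PCR scan.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    cfg = cfg or GeneratorConfig()
    start, stop, step = grid
    t = np.arange(start, stop + step / 2, step)
    pre = baseline_pre + drift_pre * (t - t[0])
    post = baseline_post + drift_post * (t - t[0])
    frac = 1.0 / (1.0 + np.exp(-(t - tm) / slope))
    y = pre + (post - pre + amplitude) * frac
    if noise_sd > 0:
        y = y + noise_sd * cfg.rng(stream=3).standard_normal(t.shape)
    return MeltCurve(temperatures=t, signal=y)


def simulate_depolymerization(
    pet_load: float = 3.75,
    volume: float = 0.150,
    plateau: float = 0.941,
    rate: float = 1.1,
    midpoint: float = 4.0,
    split: tuple[float, float, float] = (0.55, 0.45, 0.0),
    times: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    cfg: GeneratorConfig | None = None,
) -> ProductTimeCourse:
    """Logistic PET-depolymerization product time course.

    Total conversion follows extent(t) = plateau / (1 + exp(-rate*(t -
    midpoint))) (so extent(midpoint) = plateau/2), and the released moles,
    pet_load * extent / 192.17, are allocated to TPA/MHET/BHET by ``split``.
    Defaults model a pH-stat bioreactor charged with 3.75 g post-consumer PET
    in 150 mL reaching ~94 % conversion, half of it around 4 h.
    """
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must be in [0, 1]")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    cfg = cfg or GeneratorConfig()
    if times is None:
        times = np.arange(0.0, 12.5, 0.5)
    times = np.asarray(times, dtype=float)
    extent = plateau / (1.0 + np.exp(-rate * (times - midpoint)))
    total_mol = pet_load * extent / PET_REPEAT_UNIT_MASS
    if noise_sd > 0:
        rng = cfg.rng(stream=4)
        total_mol = np.clip(
            total_mol * (1.0 + noise_sd * rng.standard_normal(times.shape)), 0.0, None
        )
    return ProductTimeCourse(
        times=times,
        tpa=split[0] * total_mol,
        mhet=split[1] * total_mol,
        bhet=split[2] * total_mol,
        volume=volume,
        pet_load=pet_load,
    )
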
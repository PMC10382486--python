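"""Ramachandran-space divergence between homologs and ensemble fluctuations.

The central statistic: for each pair of aligned residues of two structures,
the Euclidean distance between their Ramachandran points,

    d = sqrt(dphi^2 + dpsi^2)   [degrees],

with the angle differences taken as minimal-image ("wrapped") differences on
the torus by default — a residue pair straddling the +/-180 seam is nearly
identical, not ~360 degrees apart. Aggregating the per-residue distances over
named regions (e.g. the active-site connecting loops of a PET hydrolase)
localizes where two backbones genuinely diverge even when the global RMSD is
small. The module also computes per-residue Ca root-mean-square fluctuations
(RMSF) of a coordinate ensemble about its mean, optionally after Kabsch
superposition of every frame onto a reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from petprofiler.geometry import TorsionProfile
from petprofiler.seq_align import AlignmentMap
from petprofiler.superpose import kabsch

__all__ = [
    "DivergenceEntry", "DivergenceProfile", "Region", "RegionSet",
    "FluctuationProfile", "wrapped_delta", "divergence_profile",
    "region_summary", "rmsf",
]


def wrapped_delta(a: float, b: float) -> float:
    """Signed minimal-image difference a - b on the circle, in [-180, 180]."""
    d = (float(a) - float(b)) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


@dataclass
class DivergenceEntry:
    key: tuple[int, str]            # residue key in the reference structure
    partner_key: tuple[int, str]    # aligned residue key in the comparator
    dphi: float = math.nan
    dpsi: float = math.nan
    distance: float = math.nan
    defined: bool = False


@dataclass
class DivergenceProfile:
    """Per-aligned-residue Ramachandran distance between two torsion profiles."""

    entries: list[DivergenceEntry] = field(default_factory=list)
    mode: str = "wrapped"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def defined_entries(self) -> list[DivergenceEntry]:
        return [e for e in self.entries if e.defined]

    def top_k(self, k: int) -> list[DivergenceEntry]:
        """The k defined entries with the largest distances (stable order on ties)."""
        return sorted(self.defined_entries(), key=lambda e: -e.distance)[:k]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("resnum\ticode\tpartner_resnum\tpartner_icode\tdphi\tdpsi\tdistance\tdefined\n")
            for e in self.entries:
                fmt = lambda v: "" if not e.defined else f"{v:.4f}"
                fh.write(
                    f"{e.key[0]}\t{e.key[1]}\t{e.partner_key[0]}\t{e.partner_key[1]}\t"
                    f"{fmt(e.dphi)}\t{fmt(e.dpsi)}\t{fmt(e.distance)}\t{int(e.defined)}\n"
                )

    def as_bfactor_values(self, chain_id: str) -> dict[tuple[str, int, str], float]:
        """Per-residue values keyed for the annotated-PDB (putty) writer."""
        return {
            (chain_id, e.key[0], e.key[1]): e.distance
            for e in self.entries if e.defined
        }


@dataclass
class Region:
    name: str
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} > end {self.end}")

    def contains(self, key: tuple[int, str]) -> bool:
        return self.start <= key[0] <= self.end


@dataclass
class RegionSet:
    """Named residue ranges, e.g. the active-site connecting loops."""

    regions: list[Region] = field(default_factory=list)

    def __iter__(self):
        return iter(self.regions)

    @classmethod
    def from_dict(cls, d: dict[str, tuple[str, int, int]]) -> "RegionSet":
        return cls([Region(name, chain, start, end)
                    for name, (chain, start, end) in d.items()])


def divergence_profile(
    tA: TorsionProfile,
    tB: TorsionProfile,
    align_map: AlignmentMap,
    mode: str = "wrapped",
) -> DivergenceProfile:
    """Ramachandran distance for every aligned residue pair.

    ``mode='wrapped'`` (default) takes minimal-image angle differences;
    ``mode='unwrapped'`` takes raw differences, inflating divergence across
    the +/-180 seam (kept for literal reproduction of naive pipelines).
    Pairs with phi or psi undefined on either side are flagged
    ``defined=False``; omega is deliberately not part of the distance.
    """
    if mode not in ("wrapped", "unwrapped"):
        raise ValueError(f"unknown mode {mode!r}")
    profile = DivergenceProfile(mode=mode)
    for ia, ib in align_map.pairs:
        ea = tA.by_position(ia)
        eb = tB.by_position(ib)
        entry = DivergenceEntry(key=ea.key, partner_key=eb.key)
        if None not in (ea.phi, eb.phi, ea.psi, eb.psi):
            if mode == "wrapped":
                dphi = wrapped_delta(ea.phi, eb.phi)
                dpsi = wrapped_delta(ea.psi, eb.psi)
            else:
                dphi = ea.phi - eb.phi
                dpsi = ea.psi - eb.psi
            entry.dphi = dphi
            entry.dpsi = dpsi
            entry.distance = math.hypot(dphi, dpsi)
            entry.defined = True
        profile.entries.append(entry)
    return profile


def region_summary(d: DivergenceProfile, regions: RegionSet) -> dict[str, dict]:
    """Mean/max Ramachandran distance and defined-residue count per region.

    Regions with no defined residue report ``count 0`` and missing (NaN)
    statistics rather than an error: disordered loop stretches are routine.
    """
    out: dict[str, dict] = {}
    for region in regions:
        dists = [e.distance for e in d.defined_entries() if region.contains(e.key)]
        out[region.name] = {
            "count": len(dists),
            "mean": float(np.mean(dists)) if dists else math.nan,
            "max": float(np.max(dists)) if dists else math.nan,
        }
    return out


@dataclass
class FluctuationProfile:
    """Per-residue Ca RMSF (Angstrom) over an ensemble of frames."""

    entries: list[tuple[tuple[int, str], float]] = field(default_factory=list)
    n_frames: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("resnum\ticode\trmsf\n")
            for (num, icode), v in self.entries:
                fh.write(f"{num}\t{icode}\t{v:.4f}\n")


def rmsf(
    frames: np.ndarray | Sequence[np.ndarray],
    reference: np.ndarray,
    presuperpose: bool = True,
    residue_keys: Sequence[tuple[int, str]] | None = None,
) -> FluctuationProfile:
    """Root-mean-square fluctuation of each position over an ensemble.

    ``frames`` is (n_frames, n_res, 3) for a fixed Ca selection; if
    ``presuperpose`` each frame is first Kabsch-fitted onto ``reference``
    over the full selection (standard trajectory practice, removing global
    rotation/translation). The fluctuation is measured about the per-residue
    mean position of the (fitted) frames:

        rmsf_i = sqrt( mean_t |r_i(t) - <r_i>|^2 ).
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must be an (n_frames, n_res, 3) array")
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if reference.shape != frames.shape[1:]:
        raise ValueError("reference selection length does not match frames")
    if frames.shape[1] < 3:
        raise ValueError("selection must contain at least 3 positions")

    if presuperpose:
        fitted = np.empty_like(frames)
        for k in range(frames.shape[0]):
            r = kabsch(frames[k], reference)
            fitted[k] = r.transform(frames[k])
    else:
        fitted = frames

    mean_pos = fitted.mean(axis=0)
    sq = np.sum((fitted - mean_pos) ** 2, axis=2).mean(axis=0)
    values = np.sqrt(sq)
    keys = (list(residue_keys) if residue_keys is not None
            else [(i + 1, "") for i in range(frames.shape[1])])
    if len(keys) != frames.shape[1]:
        raise ValueError("residue_keys length does not match selection")
    return FluctuationProfile(entries=list(zip(keys, values)),
                              n_frames=frames.shape[0])
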
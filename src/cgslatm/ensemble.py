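"""Time averaging of atomic spectra and summation into molecular SLATMs.

The Boltzmann-ensemble average of a bead's spectrum is approximated by an
arithmetic time average over trajectory snapshots (ergodicity).  Each frame
is first reduced to the solute-centered local environment, every solute
bead's spectrum is computed per frame, and the per-bead averages are then
summed over the molecule into a single molecular representation keyed by
interaction channel: the one-body block becomes per-type counts times Z,
per-center two-body contributions (center type I toward neighbour type J)
pool into the unordered channel {I, J}, and triplet contributions pool
into (center type, unordered neighbour pair).

Averaging before summing follows the definition of the molecular spectrum;
the two commute for arithmetic means.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .io import DEFAULT_SHELL_RADIUS, TrajectoryEnsemble, extract_local_environment
from .registry import BeadTypeRegistry, ChannelIndex, channel_key_to_str
from .slatm import AtomicSpectrum, SlatmParams, _atomic_contributions

__all__ = [
    "EnsembleSpectra",
    "MolecularSLATM",
    "ensemble_average",
    "molecular_sum",
    "save_molecular",
    "load_molecular",
]


@dataclass
class EnsembleSpectra:
    """Per-solute-bead, frame-averaged atomic spectra."""

    spectra: list[AtomicSpectrum]
    n_frames_used: int
    params: SlatmParams
    registry: BeadTypeRegistry


@dataclass
class MolecularSLATM:
    """Ensemble-averaged, solute-summed spectrum keyed by channel.

    ``channels`` maps every channel key of the index to a scalar (one-body)
    or histogram vector (two-/three-body).
    """

    channels: dict
    n_frames_used: int
    solute_bead_count: int
    params: SlatmParams
    channel_index: ChannelIndex

    def __post_init__(self) -> None:
        if self.n_frames_used < 1:
            raise ValueError("n_frames_used must be >= 1")


def ensemble_average(
    traj: TrajectoryEnsemble,
    params: SlatmParams,
    registry: BeadTypeRegistry,
    channel_index: ChannelIndex,
    radius: float = DEFAULT_SHELL_RADIUS,
    include_solute_solute: bool = True,
) -> EnsembleSpectra:
    """Arithmetic mean over frames of each solute bead's spectrum.

    Frames are passed through :func:`extract_local_environment` first.
    ``include_solute_solute=False`` removes other solute beads from every
    center's neighbourhood (ablation switch; by default intramolecular
    structure is encoded, since SLATM ignores covalent bonding).
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    n_sol = int(traj.frames[0].solute_flags.sum())
    if n_sol == 0:
        raise ValueError("trajectory has no solute beads")

    n2, n3 = params.n_bins_r, params.n_bins_theta
    # running sums per solute bead, present-channel only
    two_sums = [dict() for _ in range(n_sol)]
    three_sums = [dict() for _ in range(n_sol)]
    center_types: list[str] | None = None

    for frame in traj.frames:
        local = extract_local_environment(frame, radius)
        sol_idx = local.solute_indices
        if len(sol_idx) != n_sol:
            raise ValueError("solute beads inconsistent across frames")
        types_here = [str(local.types[i]) for i in sol_idx]
        if center_types is None:
            center_types = types_here
        elif types_here != center_types:
            raise ValueError("solute bead types inconsistent across frames")
        mask = None
        if not include_solute_solute:
            mask = ~local.solute_flags
        for b, i in enumerate(sol_idx):
            two, three = _atomic_contributions(
                local, int(i), params, registry, neighbor_mask=mask
            )
            for key, vec in two.items():
                acc = two_sums[b].get(key)
                if acc is None:
                    two_sums[b][key] = vec.copy()
                else:
                    acc += vec
            for key, vec in three.items():
                acc = three_sums[b].get(key)
                if acc is None:
                    three_sums[b][key] = vec.copy()
                else:
                    acc += vec

    nf = traj.n_frames
    spectra = []
    assert center_types is not None
    for b in range(n_sol):
        two_full = {
            j: two_sums[b].get(j, np.zeros(n2)) / nf
            for j in channel_index.one_body
        }
        three_full = {
            jk: three_sums[b].get(jk, np.zeros(n3)) / nf
            for jk in channel_index.two_body
        }
        spectra.append(
            AtomicSpectrum(
                center_type=center_types[b],
                one_body=float(registry.z_of(center_types[b])),
                two_body=two_full,
                three_body=three_full,
                params=params,
            )
        )
    return EnsembleSpectra(
        spectra=spectra,
        n_frames_used=nf,
        params=params,
        registry=registry,
    )


def molecular_sum(
    ens: EnsembleSpectra | list[AtomicSpectrum],
    channel_index: ChannelIndex,
    registry: BeadTypeRegistry | None = None,
    n_frames_used: int | None = None,
) -> MolecularSLATM:
    """Sum per-bead averaged spectra into the molecular representation."""
    if isinstance(ens, EnsembleSpectra):
        spectra = ens.spectra
        registry = ens.registry
        n_frames_used = ens.n_frames_used
    else:
        spectra = list(ens)
        if registry is None:
            raise ValueError("registry required for a bare spectrum list")
        n_frames_used = 1 if n_frames_used is None else n_frames_used
    if not spectra:
        raise ValueError("need at least one solute bead spectrum")
    params = spectra[0].params
    for s in spectra[1:]:
        if s.params != params:
            raise ValueError(
                "spectra computed under different SLATM parameters"
            )

    channels: dict = {}
    for t in channel_index.one_body:
        channels[t] = 0.0
    for pair in channel_index.two_body:
        channels[pair] = np.zeros(params.n_bins_r)
    for trip in channel_index.three_body:
        channels[trip] = np.zeros(params.n_bins_theta)

    for s in spectra:
        center = s.center_type
        channels[center] += s.one_body
        for j, vec in s.two_body.items():
            key = registry.sort_pair(center, j)
            channels[key] += vec
        for jk, vec in s.three_body.items():
            key = (center, jk)
            if key not in channels:
                raise KeyError(f"channel {key} not in index")
            channels[key] += vec
    return MolecularSLATM(
        channels=channels,
        n_frames_used=int(n_frames_used),
        solute_bead_count=len(spectra),
        params=params,
        channel_index=channel_index,
    )


# ---------------------------------------------------------------------------
# Columnar serialisation: CSV of (channel, bin, value) + JSON sidecar
# ---------------------------------------------------------------------------


def save_molecular(mol: MolecularSLATM, basepath) -> None:
    base = str(basepath)
    with open(base + ".csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "bin", "value"])
        for key in mol.channel_index.keys():
            value = mol.channels[key]
            skey = channel_key_to_str(key)
            if np.isscalar(value) or np.ndim(value) == 0:
                writer.writerow([skey, 0, repr(float(value))])
            else:
                for b, v in enumerate(np.asarray(value)):
                    writer.writerow([skey, b, repr(float(v))])
    sidecar = {
        "params": mol.params.to_dict(),
        "n_frames_used": mol.n_frames_used,
        "solute_bead_count": mol.solute_bead_count,
        "triplet_policy": mol.channel_index.triplet_policy,
        "one_body": list(mol.channel_index.one_body),
        "two_body": [list(p) for p in mol.channel_index.two_body],
        "three_body": [
            [c, list(jk)] for c, jk in mol.channel_index.three_body
        ],
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_molecular(basepath) -> MolecularSLATM:
    base = str(basepath)
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    params = SlatmParams(**sidecar["params"])
    index = ChannelIndex(
        one_body=tuple(sidecar["one_body"]),
        two_body=tuple(tuple(p) for p in sidecar["two_body"]),
        three_body=tuple(
            (c, (jk[0], jk[1])) for c, jk in sidecar["three_body"]
        ),
        triplet_policy=sidecar["triplet_policy"],
    )
    raw: dict[str, list[tuple[int, float]]] = {}
    with open(base + ".csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for skey, b, v in reader:
            raw.setdefault(skey, []).append((int(b), float(v)))
    channels: dict = {}
    for key in (
        list(index.one_body) + list(index.two_body) + list(index.three_body)
    ):
        entries = sorted(raw[channel_key_to_str(key)])
        if isinstance(key, str):
            channels[key] = entries[0][1]
        else:
            channels[key] = np.array([v for _, v in entries])
    return MolecularSLATM(
        channels=channels,
        n_frames_used=sidecar["n_frames_used"],
        solute_bead_count=sidecar["solute_bead_count"],
        params=params,
        channel_index=index,
    )
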
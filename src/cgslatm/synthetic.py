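"""Synthetic two-environment bead systems with planted structure signals.

The generator emulates the study conditions of a membrane-selectivity
screen without running MD: small solutes (1-5 beads from the reduced
``T1..T5, Q0`` alphabet) surrounded by type-dependent radial shells of
lipid/solvent beads, sampled in two environment variants A and B that are
identical except for the shell of one planted (solute type, environment
type) channel.  Each compound carries a per-compound log contrast ``u_i``
on the planted channel; environment A scales that shell's mean count by
``exp(u_i)`` so that the collapsed log-difference feature recovers ``u_i``
up to sampling noise.  The planted selectivity target is then

    y_i = beta * u_i + Normal(0, noise_sd),

mimicking a transfer-free-energy difference driven by one structural
motif.  Frames are i.i.d. draws rather than dynamics: the featurizer only
requires an ensemble, and i.i.d. sampling gives exact control of the
planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Configuration, TrajectoryEnsemble, write_xyz
from .registry import BeadTypeRegistry, default_cg_registry

__all__ = [
    "ShellSpec",
    "PlantedEffect",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_compound",
    "sample_environment",
    "generate_dataset",
    "write_dataset",
]

OVERLAP_FLOOR = 2.0  # Angstrom; CG excluded volume
BOND_LENGTH = 4.7  # Angstrom; generic CG bond
BOND_ANGLE = np.deg2rad(120.0)


@dataclass(frozen=True)
class ShellSpec:
    """Radial shell of one environment type around one solute type."""

    mean_count: float
    mean_radius: float  # Angstrom
    jitter_sd: float  # Angstrom

    def __post_init__(self) -> None:
        if self.mean_count < 0 or self.mean_radius <= 0 or self.jitter_sd < 0:
            raise ValueError("invalid shell parameters")


@dataclass(frozen=True)
class PlantedEffect:
    """Planted pair-structure contrast and its coupling to the target."""

    solute_type: str = "Q0"
    env_type: str = "Nda"
    contrast_sd: float = 0.8  # SD of the per-compound log contrast u_i
    beta: float = 1.0  # target = beta * u_i + noise

    @property
    def channel(self) -> tuple[str, str]:
        return (self.solute_type, self.env_type)


def _default_shells() -> dict:
    """Stylized interface shells for the 14-type registry.

    Neutral solute beads see a generic lipid/solvent coat (P4 headgroup,
    C1 tail, POL water); the charged Q0 bead instead coordinates the Nda
    headgroup in a tight shell -- the planted, environment-dependent motif.
    """
    shells: dict = {}
    for t in ("T1", "T2", "T3", "T4", "T5"):
        shells[(t, "P4")] = ShellSpec(3.0, 5.5, 0.8)
        shells[(t, "C1")] = ShellSpec(3.0, 6.5, 0.8)
        shells[(t, "POL")] = ShellSpec(3.0, 6.0, 0.8)
    shells[("Q0", "Nda")] = ShellSpec(6.0, 4.5, 0.8)
    return shells


def _default_bath() -> dict:
    """Uniform background densities (beads/A^3) inside the sampling sphere.

    A condensed-phase environment keeps every common type present around
    the whole solute in every frame, so channel populations are systematic
    rather than rare events; the planted Nda headgroup type is deliberately
    absent from the bath and enters only through its shell.
    """
    return {"POL": 0.004, "C1": 0.003, "P4": 0.002}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic two-environment screen."""

    n_compounds: int = 200
    beads_min: int = 1
    beads_max: int = 5
    solute_alphabet: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "Q0")
    shells: dict = field(default_factory=_default_shells)
    bath: dict = field(default_factory=_default_bath)
    bath_radius: float = 12.0  # Angstrom, around the solute centroid
    planted: PlantedEffect | None = field(default_factory=PlantedEffect)
    contrast_mode: str = "normal"  # or "bimodal" (two separable basins)
    noise_sd: float | None = None  # None: 25% of the planted signal SD
    n_frames: int = 50
    seed: int = 0
    env_labels: tuple[str, str] = ("A", "B")
    branch_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 1 <= self.beads_min <= self.beads_max:
            raise ValueError("invalid bead count range")
        if not self.solute_alphabet:
            raise ValueError("empty solute alphabet")
        if self.contrast_mode not in ("normal", "bimodal"):
            raise ValueError(f"unknown contrast_mode {self.contrast_mode!r}")
        if self.planted is not None and self.planted.channel not in self.shells:
            raise ValueError(
                f"planted channel {self.planted.channel} has no shell spec"
            )

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        if self.planted is None:
            return 0.1
        return 0.25 * abs(self.planted.beta) * self.planted.contrast_sd


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _unit_sphere(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_compound(spec: SyntheticSpec, compound_seed: int) -> Configuration:
    """Deterministically build one solute: a linear/branched bead graph.

    Bonds are fixed at 4.7 A, bond angles at 120 deg (generic CG geometry),
    with a random dihedral per bead; when a planted effect is set the first
    bead carries its solute type so every compound exposes the planted
    channel.  Overlaps below 2 A are rejected.
    """
    rng = _rng(compound_seed)
    n = int(rng.integers(spec.beads_min, spec.beads_max + 1))
    types = [str(rng.choice(spec.solute_alphabet)) for _ in range(n)]
    if spec.planted is not None:
        types[0] = spec.planted.solute_type

    pos = np.zeros((n, 3))
    parents = [-1] * n
    children = [0] * n
    if n > 1:
        pos[1] = (BOND_LENGTH, 0.0, 0.0)
        parents[1] = 0
        children[0] = 1
    for i in range(2, n):
        for _ in range(100):
            # linear growth from the last bead, or branch off an earlier one
            if rng.random() < spec.branch_probability:
                candidates = [j for j in range(i) if children[j] < 3]
                parent = int(rng.choice(candidates))
            else:
                parent = i - 1
            gp = parents[parent]
            # reference bond for the 120 deg angle: parent->grandparent,
            # or parent->first-child when the parent is the root bead
            ref = pos[1] - pos[0] if gp < 0 else pos[gp] - pos[parent]
            ref = ref / np.linalg.norm(ref)
            # direction making the bond angle with the parent->ref bond
            e1 = np.cross(ref, _unit_sphere(rng)[0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(ref, e1)
            phi = rng.uniform(0, 2 * np.pi)
            direction = np.cos(BOND_ANGLE) * ref + np.sin(BOND_ANGLE) * (
                np.cos(phi) * e1 + np.sin(phi) * e2
            )
            cand = pos[parent] + BOND_LENGTH * direction
            d = np.linalg.norm(pos[:i] - cand, axis=1)
            d[parent] = np.inf
            if (d >= OVERLAP_FLOOR).all():
                pos[i] = cand
                parents[i] = parent
                children[parent] += 1
                break
        else:
            raise RuntimeError("could not place solute bead without overlap")
    return Configuration(
        positions=pos,
        types=np.array(types, dtype=object),
        solute_flags=np.ones(n, dtype=bool),
    )


def sample_environment(
    solute: Configuration,
    env_label: str,
    spec: SyntheticSpec,
    frame_seed,
    count_scale: dict | None = None,
) -> Configuration:
    """Draw one i.i.d. environment frame around a solute.

    For each (solute bead, environment type) with a shell spec, bead counts
    are Poisson with the shell mean (optionally rescaled per channel via
    ``count_scale``), radii are normal around the shell radius, directions
    uniform on the sphere.  Placements closer than 2 A to any existing bead
    are rejected with bounded retries.
    """
    if env_label not in spec.env_labels:
        raise ValueError(f"unknown environment label {env_label!r}")
    rng = _rng(*np.atleast_1d(frame_seed))
    positions = [solute.positions]
    types = list(solute.types)
    count_scale = count_scale or {}
    all_pos = solute.positions.copy()
    for b in range(solute.n_beads):
        s_type = str(solute.types[b])
        center = solute.positions[b]
        for (st, et), shell in spec.shells.items():
            if st != s_type:
                continue
            lam = shell.mean_count * count_scale.get((st, et), 1.0)
            count = int(rng.poisson(lam))
            for _ in range(count):
                for _ in range(120):
                    r = rng.normal(shell.mean_radius, shell.jitter_sd)
                    r = max(r, OVERLAP_FLOOR)
                    cand = center + r * _unit_sphere(rng)[0]
                    d = np.linalg.norm(all_pos - cand, axis=1)
                    if (d >= OVERLAP_FLOOR).all():
                        break
                else:
                    raise RuntimeError(
                        "infeasible packing: could not place environment bead"
                    )
                all_pos = np.vstack([all_pos, cand])
                types.append(et)
    # uniform condensed-phase bath inside the sampling sphere
    centroid = solute.positions.mean(axis=0)
    volume = 4.0 / 3.0 * np.pi * spec.bath_radius**3
    for et, density in spec.bath.items():
        count = int(rng.poisson(density * volume))
        if count == 0:
            continue
        # uniform in the sphere: direction times radius ~ U^(1/3) * R
        radii = spec.bath_radius * rng.random(count) ** (1.0 / 3.0)
        cand = centroid + radii[:, None] * _unit_sphere(rng, count)
        for c in cand:
            d = np.linalg.norm(all_pos - c, axis=1)
            if (d >= OVERLAP_FLOOR).all():
                all_pos = np.vstack([all_pos, c])
                types.append(et)
    flags = np.zeros(len(all_pos), dtype=bool)
    flags[: solute.n_beads] = True
    return Configuration(
        positions=all_pos, types=np.array(types, dtype=object), solute_flags=flags
    )


@dataclass
class SyntheticDataset:
    """In-memory dataset: trajectories, metadata and the planted truth."""

    spec: SyntheticSpec
    registry: BeadTypeRegistry
    trajectories: dict  # compound_id -> {env_label: TrajectoryEnsemble}
    metadata: pd.DataFrame
    truth: dict

    @property
    def compound_ids(self) -> list[str]:
        return list(self.metadata["compound_id"])


def _draw_contrast(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    sd = spec.planted.contrast_sd
    if spec.contrast_mode == "normal":
        # truncated at +-1.5 SD: selectivity contrasts are bounded in
        # practice and unbounded draws make extreme shells unpackable
        return float(np.clip(rng.normal(0.0, sd), -1.5 * sd, 1.5 * sd))
    # bimodal: two clearly separated basins at +-sd with narrow spread
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return float(sign * sd * (1.0 + 0.2 * abs(rng.normal())))


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate compounds, paired-environment trajectories and targets.

    Environment A carries the planted count contrast ``exp(u_i)`` on the
    planted channel; environment B is the unmodified reference.  The truth
    record stores beta, the planted channel and every per-compound
    contrast, so recovery can be scored exactly.
    """
    registry = default_cg_registry()
    label_a, label_b = spec.env_labels
    noise_sd = spec.effective_noise_sd
    rng = _rng(spec.seed, 0xD5)

    trajectories: dict = {}
    rows = []
    contrasts = []
    for i in range(spec.n_compounds):
        cid = f"cmp{i:04d}"
        solute = generate_compound(spec, compound_seed=_seed_int(spec.seed, i))
        u = _draw_contrast(spec, rng) if spec.planted is not None else 0.0
        contrasts.append(u)
        scale_a = (
            {spec.planted.channel: float(np.exp(u))}
            if spec.planted is not None
            else {}
        )
        frames_a, frames_b = [], []
        for f in range(spec.n_frames):
            frames_a.append(
                sample_environment(
                    solute, label_a, spec, (spec.seed, i, 0, f), scale_a
                )
            )
            frames_b.append(
                sample_environment(
                    solute, label_b, spec, (spec.seed, i, 1, f), None
                )
            )
        trajectories[cid] = {
            label_a: TrajectoryEnsemble(frames_a),
            label_b: TrajectoryEnsemble(frames_b),
        }
        types = list(solute.types)
        beta = spec.planted.beta if spec.planted is not None else 0.0
        y = beta * u + float(rng.normal(0.0, noise_sd))
        rows.append(
            {
                "compound_id": cid,
                "bead_count": solute.n_beads,
                "n_polar": sum(t in ("T1", "T2") for t in types),
                "n_charged": sum(t == "Q0" for t in types),
                "n_hbond": sum(t == "T3" for t in types),
                "ddG": y,
            }
        )
    metadata = pd.DataFrame(rows)
    truth = {
        "beta": spec.planted.beta if spec.planted is not None else 0.0,
        "channel": list(spec.planted.channel)
        if spec.planted is not None
        else None,
        "contrasts": contrasts,
        "noise_sd": noise_sd,
        "seed": spec.seed,
        "contrast_mode": spec.contrast_mode,
    }
    return SyntheticDataset(
        spec=spec,
        registry=registry,
        trajectories=trajectories,
        metadata=metadata,
        truth=truth,
    )


def _seed_int(seed: int, i: int) -> int:
    """Stable per-compound integer seed below 2**31."""
    return int(
        np.random.SeedSequence([seed, i]).generate_state(1, np.uint32)[0]
        % (2**31)
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write the file layout the real pipeline consumes.

    Per compound and environment an extended-XYZ trajectory, plus the
    registry TOML, the metadata CSV and the planted-truth JSON.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cid, envs in dataset.trajectories.items():
        for label, traj in envs.items():
            write_xyz(out / f"{cid}_{label}.xyz", traj)
    dataset.registry.to_toml(out / "registry.toml")
    dataset.metadata.to_csv(out / "metadata.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
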
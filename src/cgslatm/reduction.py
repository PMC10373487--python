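"""Channel collapse, log transform and two-environment difference vectors.

Each two-/three-body channel of a molecular SLATM is a histogram; for the
structure-property analysis it is collapsed to one scalar per channel.
Because the London/ATM power laws spread channel magnitudes over orders of
magnitude, the collapsed spectrum is log-transformed, and the quantity of
interest is the difference of the log spectra between two environments
(e.g. a cardiolipin vs a phosphatidylglycerol membrane):

    delta_c = ln(s_c^A + eps) - ln(s_c^B + eps)

with A the target environment and B the reference.  The difference is
antisymmetric under swapping environments and invariant under a common
rescaling of a channel.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import MolecularSLATM
from .registry import channel_key_to_str

__all__ = [
    "FeatureVector",
    "DifferenceVector",
    "collapse_channels",
    "log_difference",
    "assemble_difference_matrix",
    "build_descriptor_table",
    "save_vector",
    "load_vector_values",
]

REDUCTION_MODES = (
    "mean-mass",
    "total-mass",
    "total-abs-mass",
    "weighted-coordinate",
)
DEFAULT_EPSILON = 1e-12


@dataclass
class FeatureVector:
    """Per-channel collapsed scalars of one compound in one environment."""

    values: np.ndarray
    channel_keys: tuple
    reduction_mode: str
    epsilon: float = DEFAULT_EPSILON
    compound_id: str | None = None
    env_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.channel_keys):
            raise ValueError("values length != channel count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def D(self) -> int:
        return len(self.values)


@dataclass
class DifferenceVector:
    """Log-difference feature vector between two environments."""

    values: np.ndarray
    channel_keys: tuple
    compound_id: str | None = None
    env_pair: tuple[str, str] = ("A", "B")
    reduction_mode: str = "total-mass"
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.channel_keys):
            raise ValueError("values length != channel count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite difference values")

    @property
    def D(self) -> int:
        return len(self.values)

    @property
    def l2_norm(self) -> float:
        return float(np.linalg.norm(self.values))


def collapse_channels(
    mol: MolecularSLATM, mode: str = "total-mass"
) -> FeatureVector:
    """Collapse each channel's histogram to a scalar.

    Modes (one-body channels pass through unchanged in all of them):

    ``total-mass``
        sum of the histogram entries (default; preserves the magnitude
        heterogeneity the log transform is meant to compress),
    ``total-abs-mass``
        sum of absolute histogram entries; identical to ``total-mass`` for
        the non-negative two-body channels but stable for three-body ATM
        channels, whose net mass can hover near zero with a noisy sign,
    ``mean-mass``
        total mass divided by the number of bins,
    ``weighted-coordinate``
        mass-weighted mean bin coordinate, 0 for empty channels.
    """
    if mode not in REDUCTION_MODES:
        raise ValueError(f"unknown reduction mode {mode!r}")
    index = mol.channel_index
    params = mol.params
    keys = tuple(index.keys())
    values = np.empty(len(keys))
    coords = {
        "two": params.r_bin_centers,
        "three": params.theta_bin_centers,
    }
    for pos, key in enumerate(keys):
        value = mol.channels[key]
        if np.ndim(value) == 0:
            values[pos] = float(value)
            continue
        h = np.asarray(value, dtype=float)
        total = h.sum()
        if mode == "total-mass":
            values[pos] = total
        elif mode == "total-abs-mass":
            values[pos] = np.abs(h).sum()
        elif mode == "mean-mass":
            values[pos] = total / len(h)
        else:  # weighted-coordinate
            if total == 0.0:
                values[pos] = 0.0
            else:
                u = coords["two" if isinstance(key[1], str) else "three"]
                values[pos] = float((h * u).sum() / total)
    return FeatureVector(values=values, channel_keys=keys, reduction_mode=mode)


def log_difference(
    fv_a: FeatureVector,
    fv_b: FeatureVector,
    epsilon: float = DEFAULT_EPSILON,
    signed: bool = False,
    compound_id: str | None = None,
    env_pair: tuple[str, str] = ("A", "B"),
) -> DifferenceVector:
    """Difference of the log-transformed collapsed spectra, A minus B.

    With ``signed=False`` (default) scalars are assumed non-negative and
    ``delta = ln(s_A + eps) - ln(s_B + eps)``; scalars at or below ``-eps``
    (possible for net-negative three-body channels) raise with a pointer to
    the signed-log option ``sign(s) * ln(|s| + eps)``.
    """
    if fv_a.channel_keys != fv_b.channel_keys:
        raise ValueError("feature vectors use different channel indices")
    if fv_a.reduction_mode != fv_b.reduction_mode:
        raise ValueError("feature vectors use different reduction modes")
    a, b = fv_a.values, fv_b.values
    if signed:
        ta = np.sign(a) * np.log(np.abs(a) + epsilon)
        tb = np.sign(b) * np.log(np.abs(b) + epsilon)
    else:
        if (a <= -epsilon).any() or (b <= -epsilon).any():
            raise ValueError(
                "negative collapsed scalars encountered; pass signed=True "
                "to use the signed log sign(s)*ln(|s|+eps)"
            )
        ta = np.log(np.maximum(a, 0.0) + epsilon)
        tb = np.log(np.maximum(b, 0.0) + epsilon)
    return DifferenceVector(
        values=ta - tb,
        channel_keys=fv_a.channel_keys,
        compound_id=compound_id,
        env_pair=env_pair,
        reduction_mode=fv_a.reduction_mode,
        epsilon=epsilon,
    )


def assemble_difference_matrix(
    diffs: list[DifferenceVector], policy: str = "observed-only"
):
    """Stack difference vectors into an (n, D) matrix with a row manifest.

    Under ``policy="observed-only"`` channels that are exactly zero across
    every compound (never observed in either environment) are dropped;
    ``policy="all"`` keeps the full index.  Returns
    ``(matrix, kept_channel_keys, manifest)`` where the manifest is a
    DataFrame aligning rows with compound ids and environment pairs.
    """
    if not diffs:
        raise ValueError("no difference vectors")
    keys = diffs[0].channel_keys
    for d in diffs[1:]:
        if d.channel_keys != keys:
            raise ValueError("difference vectors use different channels")
    X = np.vstack([d.values for d in diffs])
    if policy == "observed-only":
        observed = ~(X == 0.0).all(axis=0)
        X = X[:, observed]
        kept = tuple(k for k, o in zip(keys, observed) if o)
    elif policy == "all":
        kept = keys
    else:
        raise ValueError(f"unknown policy {policy!r}")
    manifest = pd.DataFrame(
        {
            "row": np.arange(len(diffs)),
            "compound_id": [d.compound_id for d in diffs],
            "env_a": [d.env_pair[0] for d in diffs],
            "env_b": [d.env_pair[1] for d in diffs],
        }
    )
    return X, kept, manifest


def build_descriptor_table(
    metadata: pd.DataFrame,
    diffs: list[DifferenceVector] | None = None,
    count_columns: tuple[str, ...] = ("n_polar", "n_charged", "n_hbond"),
    bead_count_column: str = "bead_count",
) -> pd.DataFrame:
    """Per-compound descriptor table, normalized by solute bead count.

    Count descriptors (polar T1/T2, charged Q0, hydrogen-bond-proxy T3),
    the optional water-octanol partitioning column ``dG_W_Ol`` and the l2
    norm of the difference vector are each divided by the number of solute
    beads, exactly once.  Target property columns (``ddG``) are left on
    their native scale.
    """
    out = metadata.copy()
    if bead_count_column not in out:
        raise ValueError(f"metadata lacks {bead_count_column!r}")
    n = out[bead_count_column].to_numpy(dtype=float)
    if (n <= 0).any():
        raise ValueError("bead counts must be positive")
    if diffs is not None:
        if len(diffs) != len(out):
            raise ValueError("one difference vector per metadata row required")
        out["l2_norm"] = [d.l2_norm for d in diffs]
    for col in list(count_columns) + ["dG_W_Ol", "l2_norm"]:
        if col in out:
            out[col + "_per_bead"] = out[col].to_numpy(dtype=float) / n
    return out


# ---------------------------------------------------------------------------
# CSV + sidecar serialisation for feature/difference vectors
# ---------------------------------------------------------------------------


def save_vector(vec: FeatureVector | DifferenceVector, basepath) -> None:
    base = str(basepath)
    with open(base + ".csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "value"])
        for key, v in zip(vec.channel_keys, vec.values):
            writer.writerow([channel_key_to_str(key), repr(float(v))])
    meta = {
        "kind": type(vec).__name__,
        "reduction_mode": vec.reduction_mode,
        "epsilon": vec.epsilon,
        "compound_id": vec.compound_id,
    }
    if isinstance(vec, DifferenceVector):
        meta["env_pair"] = list(vec.env_pair)
    else:
        meta["env_label"] = vec.env_label
    with open(base + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_vector_values(basepath) -> tuple[np.ndarray, list[str], dict]:
    base = str(basepath)
    keys, values = [], []
    with open(base + ".csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for k, v in reader:
            keys.append(k)
            values.append(float(v))
    with open(base + ".json") as fh:
        meta = json.load(fh)
    return np.array(values), keys, meta
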
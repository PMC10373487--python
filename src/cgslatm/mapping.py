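"""PCA structure-property mapping over log-difference SLATM features.

The model is deliberately linear: PCA finds the orthogonal directions of
maximal variance of the zero-mean (n x D) difference matrix by solving the
eigenproblem of its covariance, and single principal components (PCs) are
then correlated against thermodynamic or physicochemical descriptors by
ordinary least squares.  Interpretation goes through the *scaled loadings*
``l_kc = v_kc * sqrt(lambda_k)`` -- eigenvector entries magnified by the
component's standard deviation, so that the covariance between channel c
and score k is recovered as ``cov(X_c, Y_k) = lambda_k * v_kc``.  Dominant
channels are read off above an absolute scaled-loading threshold, pooled
into bead-type interaction graphs, and pairs of PCs give 2-D selectivity
maps (biplots) onto which unseen compounds are projected and classified.

Organised statsmodels-style: :class:`SelectivityMap` holds the data and
``fit()`` returns a :class:`SelectivityMapResults` carrying estimates,
diagnostics and ``summary()``.
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .reduction import DifferenceVector, assemble_difference_matrix
from .registry import (
    BeadTypeRegistry,
    channel_key_from_str,
    channel_key_to_str,
)

__all__ = [
    "SelectivityMap",
    "SelectivityMapResults",
    "Correlation",
    "build_interaction_graph",
    "write_graphml",
    "write_dot",
    "plot_chart",
]

Correlation = namedtuple("Correlation", ["r2", "slope", "intercept"])

DEFAULT_LOADING_THRESHOLD = 1.0  # on the scaled-loading scale
DEFAULT_N_ARROWS = 6

# randomized SVD pays off only for large matrices; both branches are seeded
_RANDOMIZED_SIZE = 2_000_000


class SelectivityMap:
    """PCA-based structure-property map (the model object).

    Parameters
    ----------
    X : (n, D) array
        Difference matrix; rows are compounds, columns channels.
    channel_keys : sequence
        Channel key per column (registry names / pairs / triplets).
    compound_ids, descriptors : optional
        Row labels and a per-compound descriptor DataFrame aligned with
        the rows (targets such as ddG, counts per bead, l2 norm, ...).
    registry : optional
        Bead-type registry; needed for interaction graphs.
    """

    def __init__(
        self,
        X,
        channel_keys,
        compound_ids=None,
        descriptors: pd.DataFrame | None = None,
        registry: BeadTypeRegistry | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.channel_keys = tuple(channel_keys)
        if len(self.channel_keys) != self.X.shape[1]:
            raise ValueError("one channel key per column required")
        n = self.X.shape[0]
        self.compound_ids = (
            list(compound_ids) if compound_ids is not None else list(range(n))
        )
        if len(self.compound_ids) != n:
            raise ValueError("one compound id per row required")
        if descriptors is not None and len(descriptors) != n:
            raise ValueError("descriptor table must align with rows")
        self.descriptors = descriptors
        self.registry = registry

    @classmethod
    def from_differences(
        cls,
        diffs: list[DifferenceVector],
        descriptors: pd.DataFrame | None = None,
        policy: str = "observed-only",
        registry: BeadTypeRegistry | None = None,
    ) -> "SelectivityMap":
        X, kept, manifest = assemble_difference_matrix(diffs, policy=policy)
        return cls(
            X,
            kept,
            compound_ids=list(manifest["compound_id"]),
            descriptors=descriptors,
            registry=registry,
        )

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def fit(
        self, n_components: int, seed: int = 0, svd_solver: str | None = None
    ) -> "SelectivityMapResults":
        """Fit the PCA map with ``n_components`` retained directions.

        Columns are centered by their stored means; no whitening or
        variance scaling is applied.  The decomposition is seeded and
        sign-fixed (largest-|entry| of each eigenvector positive) so output
        is reproducible bit-for-bit; randomized SVD is selected
        automatically for large matrices.
        """
        n, D = self.X.shape
        if n < 2:
            raise ValueError("need at least two compounds")
        if not 1 <= n_components <= min(n, D):
            raise ValueError(
                f"n_components must be in 1..{min(n, D)}, got {n_components}"
            )
        centered = self.X - self.X.mean(axis=0)
        if not np.any(np.abs(centered) > 0):
            raise ValueError("constant matrix: zero total variance")
        if svd_solver is None:
            svd_solver = (
                "randomized" if self.X.size > _RANDOMIZED_SIZE else "full"
            )
        pca = PCA(
            n_components=n_components,
            svd_solver=svd_solver,
            whiten=False,
            random_state=int(seed),
        )
        scores = pca.fit_transform(self.X)
        components = pca.components_.copy()  # (d, D)
        # deterministic sign convention: largest-|entry| positive
        for k in range(n_components):
            j = int(np.argmax(np.abs(components[k])))
            if components[k, j] < 0:
                components[k] *= -1.0
                scores[:, k] *= -1.0
        return SelectivityMapResults(
            model=self,
            column_means=pca.mean_.copy(),
            eigenvalues=pca.explained_variance_.copy(),
            components=components,
            scores=scores,
            explained_variance_ratio=pca.explained_variance_ratio_.copy(),
            seed=int(seed),
        )


@dataclass
class SelectivityMapResults:
    """Fitted PCA map: eigenpairs, scores and interpretation tools."""

    model: SelectivityMap
    column_means: np.ndarray
    eigenvalues: np.ndarray  # lambda_k, descending (sample variance, ddof=1)
    components: np.ndarray  # (d, D), unit-norm rows, sign-fixed
    scores: np.ndarray  # (n, d)
    explained_variance_ratio: np.ndarray
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def channel_keys(self) -> tuple:
        return self.model.channel_keys

    # -- projection ---------------------------------------------------------
    def project(self, new_vectors) -> np.ndarray:
        """Project new difference vectors onto the eigenvectors, Y = X V.

        :class:`DifferenceVector` inputs are aligned to the model's channel
        set by key (channels pruned at fit time are ignored), so vectors
        carrying the full channel index project correctly.
        """
        if isinstance(new_vectors, DifferenceVector):
            new_vectors = self._align(new_vectors)
        elif (
            isinstance(new_vectors, (list, tuple))
            and new_vectors
            and isinstance(new_vectors[0], DifferenceVector)
        ):
            new_vectors = np.vstack([self._align(d) for d in new_vectors])
        x = np.asarray(new_vectors, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != len(self.column_means):
            raise ValueError(
                f"dimension mismatch: got {x.shape[1]} channels, "
                f"model has {len(self.column_means)}"
            )
        y = (x - self.column_means) @ self.components.T
        return y[0] if squeeze else y

    def _align(self, d: DifferenceVector) -> np.ndarray:
        if d.channel_keys == self.channel_keys:
            return d.values
        lookup = {k: v for k, v in zip(d.channel_keys, d.values)}
        missing = [k for k in self.channel_keys if k not in lookup]
        if missing:
            raise ValueError(
                f"difference vector lacks {len(missing)} model channels, "
                f"e.g. {channel_key_to_str(missing[0])}"
            )
        return np.array([lookup[k] for k in self.channel_keys])

    def reconstruct(self, scores=None) -> np.ndarray:
        """Back-transform scores to channel space (lossless at d = D)."""
        y = self.scores if scores is None else np.atleast_2d(scores)
        return y @ self.components + self.column_means

    # -- loadings -----------------------------------------------------------
    def scaled_loadings(self, k: int) -> pd.DataFrame:
        """Channel table of PC ``k`` loadings scaled by sqrt(lambda_k).

        Sorted by |scaled loading| descending; exact ties fall back to the
        lexicographic order of the channel key string.
        """
        self._check_k(k)
        raw = self.components[k]
        scaled = raw * np.sqrt(self.eigenvalues[k])
        df = pd.DataFrame(
            {
                "channel": [channel_key_to_str(c) for c in self.channel_keys],
                "loading": raw,
                "scaled_loading": scaled,
            }
        )
        df["_abs"] = np.abs(df["scaled_loading"])
        df = (
            df.sort_values(["_abs", "channel"], ascending=[False, True])
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
        return df

    def dominant_interactions(
        self,
        k: int,
        threshold: float = DEFAULT_LOADING_THRESHOLD,
        sign: str = "both",
    ) -> list:
        """Channels whose scaled loading on PC ``k`` passes the threshold.

        ``sign`` selects ``"negative"`` (l <= -threshold), ``"positive"``
        (l >= threshold) or ``"both"`` (|l| >= threshold); the default
        threshold of 1.0 mirrors common reporting practice for dominant
        loadings.  Returns channel keys sorted by |scaled loading|.
        """
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        if sign not in ("negative", "positive", "both"):
            raise ValueError(f"unknown sign filter {sign!r}")
        table = self.scaled_loadings(k)
        sl = table["scaled_loading"]
        if sign == "negative":
            table = table[sl <= -threshold]
        elif sign == "positive":
            table = table[sl >= threshold]
        else:
            table = table[sl.abs() >= threshold]
        return [channel_key_from_str(c) for c in table["channel"]]

    def one_body_share(self, k: int) -> float:
        """Fraction of PC ``k``'s squared loading mass on one-body channels.

        Diagnostic: with near-identical type populations in both
        environments, one-body contributions should be virtually
        negligible; they are retained in the matrix, not dropped.
        """
        self._check_k(k)
        is_one = np.array(
            [isinstance(c, str) for c in self.channel_keys], dtype=bool
        )
        v2 = self.components[k] ** 2
        return float(v2[is_one].sum() / v2.sum())

    # -- correlation --------------------------------------------------------
    def correlate(self, k: int, descriptor) -> Correlation:
        """OLS of a descriptor on PC ``k``'s scores; returns R2 and slope.

        ``descriptor`` is a column name of the model's descriptor table or
        an explicit array.  The slope sign feeds the negative-loading logic
        when strong selectivity corresponds to negative property values.
        """
        self._check_k(k)
        y = self._descriptor_values(descriptor)
        x = self.scores[:, k]
        if len(y) != len(x):
            raise ValueError("descriptor length != number of compounds")
        if len(x) < 3:
            raise ValueError("need at least 3 points")
        if np.ptp(y) == 0:
            raise ValueError("zero-variance descriptor")
        res = stats.linregress(x, y)
        return Correlation(
            r2=float(res.rvalue**2),
            slope=float(res.slope),
            intercept=float(res.intercept),
        )

    def _descriptor_values(self, descriptor) -> np.ndarray:
        if isinstance(descriptor, str):
            if self.model.descriptors is None:
                raise ValueError("model has no descriptor table")
            return self.model.descriptors[descriptor].to_numpy(dtype=float)
        return np.asarray(descriptor, dtype=float)

    # -- graphs -------------------------------------------------------------
    def interaction_graph(
        self,
        k: int | None = None,
        channels: list | None = None,
        threshold: float = DEFAULT_LOADING_THRESHOLD,
        sign: str = "negative",
        include_pair_leg: bool = False,
    ) -> nx.Graph:
        """Bead-type interaction graph of dominant channels.

        Either pass explicit ``channels`` or a PC index ``k`` whose
        dominant channels (per ``threshold``/``sign``) are used.
        """
        if channels is None:
            if k is None:
                raise ValueError("pass either k or channels")
            channels = self.dominant_interactions(k, threshold, sign)
        if self.model.registry is None:
            raise ValueError("model has no bead-type registry")
        return build_interaction_graph(
            channels, self.model.registry, include_pair_leg=include_pair_leg
        )

    # -- 2-D maps -----------------------------------------------------------
    def chart_map(
        self,
        pc_a: int,
        pc_b: int,
        color_descriptor=None,
        n_arrows: int = DEFAULT_N_ARROWS,
    ) -> dict:
        """Plot-ready biplot bundle for a pair of PCs.

        Scores are min-max scaled per axis to [-1, 1]; the arrow set holds
        the ``n_arrows`` two-body channels with the largest combined
        |scaled loading| on the two axes, with directions (l_a, l_b).
        Returns ``{"points": DataFrame, "arrows": DataFrame}``.
        """
        if pc_a == pc_b:
            raise ValueError("pc_a and pc_b must differ")
        self._check_k(pc_a)
        self._check_k(pc_b)
        pts = {}
        for name, k in (("x", pc_a), ("y", pc_b)):
            s = self.scores[:, k]
            lo, hi = s.min(), s.max()
            if hi == lo:
                raise ValueError(f"degenerate axis PC{k}: zero variance")
            pts[name] = 2.0 * (s - lo) / (hi - lo) - 1.0
        points = pd.DataFrame(
            {
                "compound_id": self.model.compound_ids,
                "x": pts["x"],
                "y": pts["y"],
            }
        )
        if color_descriptor is not None:
            points["color"] = self._descriptor_values(color_descriptor)

        la = self.components[pc_a] * np.sqrt(self.eigenvalues[pc_a])
        lb = self.components[pc_b] * np.sqrt(self.eigenvalues[pc_b])
        rows = []
        for c, a, b in zip(self.channel_keys, la, lb):
            if isinstance(c, tuple) and isinstance(c[1], str):  # two-body
                rows.append((channel_key_to_str(c), a, b, np.hypot(a, b)))
        arrows = (
            pd.DataFrame(rows, columns=["channel", "dx", "dy", "magnitude"])
            .sort_values(["magnitude", "channel"], ascending=[False, True])
            .head(n_arrows)
            .reset_index(drop=True)
        )
        return {
            "points": points,
            "arrows": arrows,
            "pc_a": pc_a,
            "pc_b": pc_b,
        }

    def classify_new(
        self,
        pc_a: int,
        pc_b: int,
        train_labels,
        new_vectors,
        selective_label="selective",
        non_selective_label="non-selective",
    ):
        """Place new compounds on a 2-D PC map and classify selectivity.

        A least-squares separating line is fitted on the training scores
        (labels encoded +1 selective / -1 non-selective); new difference
        vectors are projected and classified by the side of the line, with
        boundary points deterministically assigned non-selective.  Returns
        ``(labels, coords, boundary_coefficients)``; the coefficients
        (a, b, c) of ``a*x + b*y + c`` are reported so the line can be
        overridden by hand.
        """
        if pc_a == pc_b:
            raise ValueError("pc_a and pc_b must differ")
        self._check_k(pc_a)
        self._check_k(pc_b)
        labels = np.asarray(list(train_labels))
        if len(labels) != len(self.scores):
            raise ValueError("one training label per fitted compound")
        enc = np.where(labels == selective_label, 1.0, -1.0)
        if labels.dtype == bool or set(np.unique(labels)) <= {0, 1, True, False}:
            enc = np.where(labels.astype(bool), 1.0, -1.0)
        if len(np.unique(enc)) < 2:
            raise ValueError("training labels contain a single class")
        A = np.column_stack(
            [self.scores[:, pc_a], self.scores[:, pc_b], np.ones(len(enc))]
        )
        coef, *_ = np.linalg.lstsq(A, enc, rcond=None)
        y = self.project(new_vectors)
        squeeze = y.ndim == 1
        y = np.atleast_2d(y)
        coords = y[:, [pc_a, pc_b]]
        h = coords @ coef[:2] + coef[2]
        # points within rounding distance of the line count as boundary,
        # and the boundary deterministically resolves to non-selective
        tol = 1e-9 * (1.0 + np.abs(coef).sum())
        out = np.where(h > tol, selective_label, non_selective_label)
        if squeeze:
            return out[0], coords[0], coef
        return out, coords, coef

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary."""
        n, D = self.model.X.shape
        lines = [
            "Selectivity map (PCA on log-difference SLATM features)",
            f"  compounds: {n}    channels: {D}    components: {self.n_components}",
            f"  seed: {self.seed}",
            "",
            "  PC   eigenvalue   expl.var   cumulative   one-body share",
        ]
        cum = 0.0
        for k in range(self.n_components):
            cum += self.explained_variance_ratio[k]
            lines.append(
                f"  {k + 1:<4d} {self.eigenvalues[k]:<12.5g} "
                f"{self.explained_variance_ratio[k]:<10.3f} {cum:<12.3f} "
                f"{self.one_body_share(k):.2e}"
            )
        if self.model.descriptors is not None:
            num = self.model.descriptors.select_dtypes("number")
            cols = [c for c in num.columns if np.ptp(num[c].to_numpy()) > 0]
            if cols:
                lines += ["", "  R2 of descriptor vs PC (OLS):"]
                header = "  " + " " * 14 + "".join(
                    f"PC{k + 1:<7d}" for k in range(self.n_components)
                )
                lines.append(header)
                for c in cols:
                    r2s = [
                        self.correlate(k, c).r2
                        for k in range(self.n_components)
                    ]
                    lines.append(
                        f"  {c:<14s}" + "".join(f"{r:<9.3f}" for r in r2s)
                    )
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Persist the fitted map as a single JSON document."""
        doc = {
            "seed": self.seed,
            "channel_keys": [
                channel_key_to_str(c) for c in self.channel_keys
            ],
            "compound_ids": [str(c) for c in self.model.compound_ids],
            "column_means": self.column_means.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "scores": self.scores.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path, model: SelectivityMap | None = None):
        with open(path) as fh:
            doc = json.load(fh)
        keys = tuple(channel_key_from_str(c) for c in doc["channel_keys"])
        scores = np.array(doc["scores"])
        if model is None:
            model = SelectivityMap(
                np.zeros((scores.shape[0], len(keys))),
                keys,
                compound_ids=doc["compound_ids"],
            )
        return cls(
            model=model,
            column_means=np.array(doc["column_means"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            components=np.array(doc["components"]),
            scores=scores,
            explained_variance_ratio=np.array(
                doc["explained_variance_ratio"]
            ),
            seed=doc["seed"],
        )

    def _check_k(self, k: int) -> None:
        if not 0 <= k < self.n_components:
            raise ValueError(
                f"component {k} out of range 0..{self.n_components - 1}"
            )


# ---------------------------------------------------------------------------
# Interaction graphs
# ---------------------------------------------------------------------------


def build_interaction_graph(
    channels: list,
    registry: BeadTypeRegistry,
    include_pair_leg: bool = False,
) -> nx.Graph:
    """Pool dominant channels into a bead-type interaction graph.

    A two-body channel {I, J} adds the edge (I, J); a three-body channel
    (I, {J, K}) adds the center-neighbour edges (I, J) and (I, K) -- and,
    with ``include_pair_leg=True``, also the neighbour-neighbour edge
    (J, K).  Edge weights count occurrences across channels, edge
    ``provenance`` lists the contributing channel keys, and nodes/edges are
    tagged by bead category (solute-solute / solute-environment / solvent).
    """
    g = nx.Graph()

    def _add_node(t):
        if t not in registry:
            raise KeyError(f"bead type {t!r} not in registry")
        g.add_node(t, category=registry.category_of(t))

    def _edge_kind(a, b):
        ca, cb = registry.category_of(a), registry.category_of(b)
        if "solvent" in (ca, cb):
            return "solvent"
        if ca == cb == "solute":
            return "solute-solute"
        return "solute-environment"

    def _add_edge(a, b, provenance):
        _add_node(a)
        _add_node(b)
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
            g[a][b]["provenance"].append(provenance)
        else:
            g.add_edge(
                a,
                b,
                weight=1,
                provenance=[provenance],
                kind=_edge_kind(a, b),
            )

    for key in channels:
        if isinstance(key, str):
            raise ValueError(
                f"one-body channel {key!r} has no pairwise counterpart"
            )
        skey = channel_key_to_str(key)
        if isinstance(key[1], str):  # two-body
            a, b = key
            _add_edge(a, b, skey)
        else:  # three-body: project onto center-neighbour edges
            center, (j, k) = key
            _add_edge(center, j, skey)
            _add_edge(center, k, skey)
            if include_pair_leg:
                _add_edge(j, k, skey)
    return g


def write_graphml(g: nx.Graph, path) -> None:
    h = g.copy()
    for _, _, data in h.edges(data=True):
        data["provenance"] = ";".join(data.get("provenance", []))
    nx.write_graphml(h, path)


def write_dot(g: nx.Graph, path) -> None:
    """Minimal DOT export (undirected, weight -> penwidth)."""
    lines = ["graph interactions {"]
    for node, data in g.nodes(data=True):
        lines.append(
            f'  "{node}" [category="{data.get("category", "")}"];'
        )
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1)
        kind = data.get("kind", "")
        style = "dashed" if kind == "solvent" else "solid"
        lines.append(
            f'  "{a}" -- "{b}" [weight={w}, penwidth={w}, style={style}];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def plot_chart(bundle: dict, ax=None):
    """Render a chart_map bundle with matplotlib (returns the axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = bundle["points"]
    color = pts["color"] if "color" in pts else None
    sc = ax.scatter(pts["x"], pts["y"], c=color, s=14, cmap="viridis")
    if color is not None:
        plt.colorbar(sc, ax=ax)
    arrows = bundle["arrows"]
    if len(arrows):
        scale = 0.9 / max(arrows["magnitude"].max(), 1e-30)
        for _, row in arrows.iterrows():
            ax.annotate(
                "",
                xy=(row.dx * scale, row.dy * scale),
                xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="crimson"),
            )
            ax.text(
                row.dx * scale, row.dy * scale, row.channel, fontsize=7
            )
    ax.set_xlabel(f"PC{bundle['pc_a'] + 1} (scaled)")
    ax.set_ylabel(f"PC{bundle['pc_b'] + 1} (scaled)")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    return ax
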
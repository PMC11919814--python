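"""Experiment container, preprocessing, and cross-sample exploration.

The :class:`Experiment` is the unit every analysis consumes: a processed
lipid x sample abundance matrix with each sample assigned to one of two
groups (case vs control).  Preprocessing follows common lipidomics
practice — drop species with too many missing values, impute the rest at
half the per-species observed minimum, optionally normalize per sample,
and work on the log2 scale thereafter — and records every step with its
parameters in a processing log, since defaults vary between labs.

Cross-sample exploration covers PCA / t-SNE / UMAP embeddings of samples
and sample-sample correlation with average-linkage hierarchical ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Experiment",
    "Embedding",
    "PreprocessOptions",
    "preprocess",
    "reduce_dimensions",
    "sample_correlation",
]

GROUPS = ("case", "control")


@dataclass
class PreprocessOptions:
    """Preprocessing knobs, all recorded in the processing log.

    max_missing_fraction : species missing in more than this fraction of
        samples are dropped (default 0.5).
    impute : "half_min" replaces missing values with half the per-species
        observed minimum; "none" requires a complete matrix.
    normalization : "none", "median" (divide each sample by its median,
        rescale to grand median), or "sum" (scale each sample to the mean
        total).
    log2 : apply log2; a pseudocount of `pseudocount` is added when zeros
        remain ("auto" uses 1 only if needed, else 0).
    """

    max_missing_fraction: float = 0.5
    impute: str = "half_min"
    normalization: str = "none"
    log2: bool = True
    pseudocount: float | str = "auto"


@dataclass
class Experiment:
    """Processed two-group lipidomics experiment.

    Attributes
    ----------
    abundance : pandas.DataFrame
        Linear-scale processed abundances (lipids x samples, no missing).
    log2 : pandas.DataFrame
        log2-transformed abundances used by all statistical tests.
    group_of : dict
        sample id -> "case" | "control"; both groups non-empty.
    processing_log : list of str
        Every applied transform with its parameters.
    """

    abundance: pd.DataFrame
    log2: pd.DataFrame
    group_of: dict[str, str]
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.abundance.columns) != list(self.log2.columns) or list(
            self.abundance.index
        ) != list(self.log2.index):
            raise ValueError("abundance and log2 matrices must be aligned")
        missing = [s for s in self.abundance.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        bad = {g for g in self.group_of.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"groups must be 'case'/'control', got {sorted(bad)}")
        for g in GROUPS:
            if not self.samples_in(g):
                raise ValueError(f"group {g!r} is empty")

    @property
    def lipid_names(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.abundance.columns if self.group_of[s] == group]

    def log2_values(self, group: str) -> pd.DataFrame:
        return self.log2[self.samples_in(group)]

    def swap_groups(self) -> "Experiment":
        """Experiment with case/control labels exchanged (for antisymmetry checks)."""
        flipped = {
            s: ("control" if g == "case" else "case") for s, g in self.group_of.items()
        }
        return Experiment(
            abundance=self.abundance,
            log2=self.log2,
            group_of=flipped,
            processing_log=self.processing_log + ["swap_groups"],
        )


@dataclass
class Embedding:
    """Low-dimensional sample embedding."""

    method: str  # "pca" | "tsne" | "umap"
    coordinates: pd.DataFrame  # samples x k
    explained_variance_ratio: list[float] | None
    seed: int


def preprocess(
    raw: pd.DataFrame,
    metadata: pd.DataFrame,
    options: PreprocessOptions | None = None,
    group_col: str = "group",
    case_label: str | None = None,
) -> Experiment:
    """Build an :class:`Experiment` from a raw abundance table and metadata.

    Parameters
    ----------
    raw : pandas.DataFrame
        Lipids x samples, nonnegative reals, NaN for missing.
    metadata : pandas.DataFrame
        Must contain ``sample_id`` and the group column; every matrix
        sample must appear exactly once.
    case_label : str, optional
        Which metadata group value is the case group.  Defaults to
        auto-detection when the labels are literally "case"/"control".
    """
    if options is None:
        options = PreprocessOptions()
    log: list[str] = []

    if "sample_id" not in metadata.columns or group_col not in metadata.columns:
        raise ValueError(f"metadata needs columns 'sample_id' and {group_col!r}")
    meta = metadata.set_index("sample_id")[group_col].astype(str)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    missing = [s for s in raw.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    labels = set(meta.loc[list(raw.columns)])
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {sorted(labels)}")
    if case_label is None:
        if labels == {"case", "control"}:
            case_label = "case"
        else:
            raise ValueError(
                f"group labels {sorted(labels)} are not 'case'/'control'; "
                "pass case_label explicitly"
            )
    elif case_label not in labels:
        raise ValueError(f"case_label {case_label!r} not among groups {sorted(labels)}")
    group_of = {
        s: ("case" if meta[s] == case_label else "control") for s in raw.columns
    }
    for g in GROUPS:
        n = sum(1 for v in group_of.values() if v == g)
        if n < 2:
            raise ValueError(f"group {g!r} has {n} samples; need at least 2")

    mat = raw.astype(float).copy()
    if (mat.fillna(0) < 0).any().any():
        raise ValueError("abundances must be nonnegative")

    # 1. drop species with excessive missingness
    frac_missing = mat.isna().mean(axis=1)
    dropped = mat.index[frac_missing > options.max_missing_fraction]
    if len(dropped):
        mat = mat.drop(index=dropped)
        log.append(
            f"drop_missing: removed {len(dropped)} species with missing fraction "
            f"> {options.max_missing_fraction} ({', '.join(map(str, dropped[:5]))}"
            f"{'...' if len(dropped) > 5 else ''})"
        )
    if mat.empty:
        raise ValueError("no species left after missing-value filtering")

    # 2. impute remaining missing values
    if mat.isna().any().any():
        if options.impute == "half_min":
            n_miss = int(mat.isna().sum().sum())
            row_min = mat.min(axis=1, skipna=True)
            if row_min.isna().any():
                raise ValueError("species with all values missing survived filtering")
            fill = pd.DataFrame(
                np.tile((row_min / 2.0).to_numpy()[:, None], (1, mat.shape[1])),
                index=mat.index,
                columns=mat.columns,
            )
            mat = mat.where(~mat.isna(), fill)
            log.append(f"impute: half_min filled {n_miss} missing values")
        elif options.impute == "none":
            raise ValueError("missing values present but imputation disabled")
        else:
            raise ValueError(f"unknown imputation {options.impute!r}")

    # 3. per-sample normalization
    if options.normalization == "median":
        med = mat.median(axis=0)
        if (med <= 0).any():
            raise ValueError("non-positive sample median; cannot median-normalize")
        mat = mat.div(med, axis=1) * float(np.median(med))
        log.append("normalize: per-sample median, rescaled to grand median")
    elif options.normalization == "sum":
        tot = mat.sum(axis=0)
        if (tot <= 0).any():
            raise ValueError("non-positive sample total; cannot sum-normalize")
        mat = mat.div(tot, axis=1) * float(tot.mean())
        log.append("normalize: per-sample total, rescaled to mean total")
    elif options.normalization != "none":
        raise ValueError(f"unknown normalization {options.normalization!r}")

    # 4. log2
    if options.log2:
        pc = options.pseudocount
        if pc == "auto":
            pc = 1.0 if (mat <= 0).any().any() else 0.0
        log2mat = np.log2(mat + pc)
        log.append(f"log2: pseudocount {pc}")
    else:
        # linear scale kept; the log2 view DE consumes is still materialized
        log2mat = np.log2(mat.clip(lower=np.nextafter(0, 1)))
        log.append("log2: view only (log2 transform disabled)")
    if not np.isfinite(log2mat.to_numpy()).all():
        raise ValueError("non-finite values after log2 transform")

    return Experiment(
        abundance=mat, log2=log2mat, group_of=group_of, processing_log=log
    )


def reduce_dimensions(exp: Experiment, method: str, k: int = 2, seed: int = 0) -> Embedding:
    """Embed samples in k dimensions (samples are the observations).

    PCA runs on the centered sample x lipid matrix and reports explained
    variance ratios; t-SNE and UMAP are stochastic, seeded, and make no
    geometry guarantee beyond determinism given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = exp.log2.to_numpy().T  # samples x lipids
    n_samples = X.shape[0]
    if method == "pca":
        from sklearn.decomposition import PCA

        if k > min(n_samples, X.shape[1]):
            raise ValueError(f"k={k} exceeds feasible dimensionality")
        model = PCA(n_components=k, svd_solver="full", random_state=seed)
        coords = model.fit_transform(X)
        evr = [float(v) for v in model.explained_variance_ratio_]
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(1.0, (n_samples - 1) / 3.0))
        model = TSNE(
            n_components=k,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            method="exact" if n_samples < 50 else "barnes_hut",
        )
        coords = model.fit_transform(X)
        evr = None
    elif method == "umap":
        import umap

        model = umap.UMAP(
            n_components=k,
            n_neighbors=min(15, n_samples - 1),
            random_state=seed,
        )
        coords = model.fit_transform(X)
        evr = None
    else:
        raise ValueError(f"unknown method {method!r}")
    frame = pd.DataFrame(
        np.asarray(coords, dtype=float),
        index=exp.samples,
        columns=[f"{method.upper()}{i + 1}" for i in range(k)],
    )
    return Embedding(method=method, coordinates=frame, explained_variance_ratio=evr, seed=seed)


def sample_correlation(
    exp: Experiment, method: str = "pearson"
) -> tuple[pd.DataFrame, list[str]]:
    """Sample-sample correlation matrix and dendrogram leaf order.

    Zero-variance samples (correlation undefined) are excluded and noted
    in the experiment's processing log.  Leaf order comes from
    average-linkage hierarchical clustering on distance 1 - r.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    mat = exp.log2
    variances = mat.var(axis=0, ddof=0)
    keep = variances[variances > 0].index.tolist()
    excluded = [s for s in mat.columns if s not in keep]
    if excluded:
        exp.processing_log.append(
            f"sample_correlation: excluded zero-variance samples {excluded}"
        )
    if len(keep) < 2:
        raise ValueError("fewer than two samples with nonzero variance")
    corr = mat[keep].corr(method=method)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr.to_numpy(), 1.0)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [corr.columns[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order
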
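"""Conversion of pre-treated profiles into a sample x descriptor table.

Four descriptor families are produced:

* even-step bin means over profile regions (ids like ``cpmas.95``,
  ``ftir.2der.51``, ``dtg.22``);
* logarithmic-step bin means of TD-NMR decays (40 bins up to 1.0 ms);
* PCA scores of each profile block, keeping components whose variance
  proportion exceeds 1% (mean-centering, no scaling);
* deconvolution parameters (Voigt area proportions and FWHMs; decay
  intensity proportions and relaxation times) plus their inverses,
  exponentials, logarithms and mutual ratios.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectra import Spectrum

__all__ = [
    "DescriptorMeta", "DescriptorTable", "BinBlock", "DescriptorConfig",
    "default_config", "bin_even", "bin_log_decay", "pca_descriptors",
    "derived_transforms", "assemble_table",
]


@dataclass(frozen=True)
class DescriptorMeta:
    """Provenance of one descriptor column."""

    id: str
    modality: str
    processing: str            # bin | pca | deconv | derived
    derivative_order: int = 0
    axis_lo: float | None = None
    axis_hi: float | None = None
    component_index: int | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.processing == "bin" and (self.axis_lo is None
                                         or self.axis_hi is None):
            raise ValueError("bin descriptors need axis bounds")


@dataclass
class DescriptorTable:
    """Samples x descriptors matrix with per-column metadata."""

    data: pd.DataFrame                    # index: sample_id, columns: ids
    meta: dict[str, DescriptorMeta]
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("descriptor table contains non-finite entries")
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValueError("duplicate descriptor ids")
        missing = set(self.data.columns) - set(self.meta)
        if missing:
            raise ValueError(f"columns without metadata: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, ids) -> "DescriptorTable":
        ids = list(ids)
        return DescriptorTable(self.data[ids].copy(),
                               {i: self.meta[i] for i in ids},
                               self.config_hash)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinBlock:
    """Even-step binning of one (modality, derivative-order) profile block.

    ``regions`` is a tuple of (lo, hi, n_bins); bin ids are 1-based and run
    consecutively across regions (matching conventions like ``ftir.2der.51``
    where the numbering skips excluded axis ranges).
    """

    name: str
    modality: str
    derivative: int
    regions: tuple[tuple[float, float, int], ...]

    @property
    def n_bins(self) -> int:
        return sum(n for _, _, n in self.regions)


@dataclass(frozen=True)
class DescriptorConfig:
    bin_blocks: tuple[BinBlock, ...]
    td_bins: int = 40
    td_t_max: float = 1.0e-3
    pca_var_threshold: float = 0.01
    sg_window: int = 11
    #: Per-modality overrides; the 1H MAS window is shorter because its
    #: resolved lines are only a few points wide.
    sg_window_overrides: tuple = (("h1_mas", 7),)

    def window_for(self, modality: str) -> int:
        return dict(self.sg_window_overrides).get(modality, self.sg_window)

    def fixed_column_count(self, n_deconv_params: int = 12) -> int:
        """Columns whose count does not depend on the data: bins, TD log
        bins, raw deconvolution parameters and their derived transforms."""
        k = n_deconv_params // 2
        derived = 2 * (3 * k + k * (k - 1))
        return (sum(b.n_bins for b in self.bin_blocks) + self.td_bins
                + n_deconv_params + derived)

    def hash(self) -> str:
        payload = {
            "bins": [[b.name, b.modality, b.derivative, list(b.regions)]
                     for b in self.bin_blocks],
            "td": [self.td_bins, self.td_t_max],
            "pca": self.pca_var_threshold,
            "sg": self.sg_window,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config() -> DescriptorConfig:
    """Default binning layout (850 fixed columns; PCA blocks bring the
    total to ~902 on default synthetic data).

    Widths are chosen to keep the characteristic peaks resolved: e.g. the
    1.824 ppm CP-MAS bins place the 176 ppm alpha-helix carbonyl in
    ``cpmas.95``/``cpmas.96`` and the 10 degC DTG bins place the 254-264 degC
    cuticle event in ``dtg.22``.
    """
    blocks = (
        BinBlock("wl", "h1_wideline", 0, ((-102.0, 102.0, 73),)),
        BinBlock("wl.2der", "h1_wideline", 2, ((-102.0, 102.0, 73),)),
        BinBlock("mas", "h1_mas", 0, ((-8.0, 14.2, 74),)),
        BinBlock("mas.2der", "h1_mas", 2, ((-8.0, 14.2, 74),)),
        BinBlock("cpmas", "c13_cpmas", 0, ((2.8, 185.2, 100),)),
        BinBlock("cpmas.2der", "c13_cpmas", 2, ((2.8, 185.2, 100),)),
        BinBlock("ftir.2der", "ftir", 2,
                 ((650.0, 1710.0, 53), (2670.0, 3390.0, 36))),
        BinBlock("dtg", "dtg", 0, ((44.0, 494.0, 45),)),
        BinBlock("dtg.2der", "dtg", 2, ((49.0, 493.0, 74),)),
    )
    return DescriptorConfig(bin_blocks=blocks)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bin_even(profile: Spectrum, region: tuple[float, float], n_bins: int,
             name: str, start_index: int = 1
             ) -> tuple[np.ndarray, list[DescriptorMeta]]:
    """Mean intensity over ``n_bins`` equal-width intervals of ``region``.

    Bins are left-closed; the last bin includes the upper bound.  An empty
    bin means the bin width undercuts the axis step and is an error.
    """
    lo, hi = region
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not lo < hi:
        raise ValueError("malformed region")
    sp = profile.ascending()
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(sp.axis, edges) - 1
    idx[sp.axis == hi] = n_bins - 1
    valid = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    if (counts == 0).any():
        empty = int(np.argmax(counts == 0)) + start_index
        raise ValueError(
            f"bin {name}.{empty} is empty: use fewer bins (width must "
            "exceed the axis step)")
    sums = np.bincount(idx[valid], weights=sp.intensity[valid],
                       minlength=n_bins)
    meta = [DescriptorMeta(id=f"{name}.{start_index + k}",
                           modality=sp.modality, processing="bin",
                           derivative_order=sp.derivative_order,
                           axis_lo=float(edges[k]), axis_hi=float(edges[k + 1]))
            for k in range(n_bins)]
    return sums / counts, meta


def bin_block_values(profile: Spectrum, block: BinBlock
                     ) -> tuple[np.ndarray, list[DescriptorMeta]]:
    """Apply all regions of a :class:`BinBlock` with consecutive ids."""
    if profile.modality != block.modality:
        raise ValueError("modality mismatch")
    if profile.derivative_order != block.derivative:
        raise ValueError("derivative-order mismatch")
    values, meta = [], []
    start = 1
    for lo, hi, n in block.regions:
        v, m = bin_even(profile, (lo, hi), n, block.name, start_index=start)
        values.append(v)
        meta.extend(m)
        start += n
    return np.concatenate(values), meta


def bin_log_decay(decay: Spectrum, n_bins: int = 40, t_max: float = 1.0e-3,
                  name: str = "td"
                  ) -> tuple[np.ndarray, list[DescriptorMeta]]:
    """Mean intensity over log-spaced time bins up to ``t_max``.

    Edges run from the first positive sample time to ``t_max`` with a
    constant ratio; the t = 0 point is assigned to the first bin.  An empty
    bin is merged rightward (recorded in the metadata formula field), which
    only occurs when the acquisition grid cannot support ``n_bins``.
    """
    sp = decay.ascending()
    pos = sp.axis[sp.axis > 0]
    if pos.size == 0:
        raise ValueError("decay has no positive time points")
    edges = np.geomspace(pos[0], t_max, n_bins + 1)
    idx = np.digitize(sp.axis, edges) - 1
    idx[sp.axis <= edges[0]] = 0
    idx[sp.axis == t_max] = n_bins - 1
    valid = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    sums = np.bincount(idx[valid], weights=sp.intensity[valid],
                       minlength=n_bins)
    values, meta = [], []
    k = 0
    index = 1
    while k < n_bins:
        j = k
        c, s = counts[k], sums[k]
        while c == 0 and j + 1 < n_bins:   # merge empty bin rightward
            j += 1
            c += counts[j]
            s += sums[j]
        if c == 0:
            raise ValueError("trailing empty logarithmic bin")
        note = None if j == k else f"merged_bins_{k + 1}_to_{j + 1}"
        if note:
            warnings.warn(f"{name}: {note}")
        values.append(s / c)
        meta.append(DescriptorMeta(
            id=f"{name}.{index}", modality=sp.modality, processing="bin",
            derivative_order=sp.derivative_order,
            axis_lo=float(edges[k]), axis_hi=float(edges[j + 1]),
            formula=note))
        k = j + 1
        index += 1
    return np.asarray(values), meta


def pca_descriptors(data, var_threshold: float = 0.01, name: str = "pc",
                    modality: str = "h1_mas", derivative: int = 0,
                    ) -> tuple[np.ndarray, list[DescriptorMeta], np.ndarray]:
    """Scores of the principal components above the variance threshold.

    Columns are mean-centered (no scaling).  Components are ordered by
    variance; each axis is oriented so its largest-|loading| element is
    positive.  Returns (scores, meta, variance proportions of the retained
    components).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    centered = X - X.mean(axis=0)
    if not (centered.std(axis=0) > 0).any():
        raise ValueError("zero-variance data block")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    keep = ratios > var_threshold
    scores, comps = scores[:, keep], pca.components_[keep]
    signs = np.sign(comps[np.arange(comps.shape[0]),
                          np.argmax(np.abs(comps), axis=1)])
    scores = scores * signs
    meta = [DescriptorMeta(id=f"{name}{k + 1}", modality=modality,
                           processing="pca", derivative_order=derivative,
                           component_index=k + 1,
                           formula=f"var={ratios[k]:.4f}")
            for k in range(scores.shape[1])]
    return scores, meta, ratios[keep]


def derived_transforms(params: dict[str, float], family: str,
                       modality: str = "h1_wideline"
                       ) -> tuple[dict[str, float], list[DescriptorMeta]]:
    """Inverses, exponentials, logarithms and mutual ratios of fit params.

    ``params`` maps short parameter names (e.g. ``a1``, ``w2``, ``t3``) to
    positive values; for a non-positive parameter the inverse/logarithm (and
    ratios with it in the denominator) are dropped with a warning rather
    than emitted as NaN.  For k parameters the full output has
    ``3k + k(k-1)`` columns.
    """
    values: dict[str, float] = {}
    meta: list[DescriptorMeta] = []

    def emit(suffix: str, formula: str, value: float) -> None:
        did = f"{family}.{suffix}"
        values[did] = float(value)
        meta.append(DescriptorMeta(id=did, modality=modality,
                                   processing="derived", formula=formula))

    names = list(params)
    for p in names:
        v = params[p]
        if v > 0:
            emit(f"inv.{p}", f"1/{p}", 1.0 / v)
            emit(f"log.{p}", f"log({p})", np.log(v))
        else:
            warnings.warn(f"{family}.{p} <= 0: inverse/log dropped")
        emit(f"exp.{p}", f"exp({p})", np.exp(v))
    for p in names:
        for q in names:
            if p == q:
                continue
            if params[q] > 0:
                emit(f"ratio.{p}.{q}", f"{p}/{q}", params[p] / params[q])
            else:
                warnings.warn(f"{family}.{q} <= 0: ratio {p}/{q} dropped")
    return values, meta


def assemble_table(blocks, sample_ids, config_hash: str = ""
                   ) -> DescriptorTable:
    """Column-concatenate (frame, meta) blocks into one DescriptorTable.

    Every block must cover exactly the given samples in the given order;
    duplicate descriptor ids are an error.
    """
    sample_ids = list(sample_ids)
    frames, meta = [], {}
    for frame, block_meta in blocks:
        if list(frame.index) != sample_ids:
            raise ValueError("block sample set/order mismatch")
        for m in block_meta:
            if m.id in meta:
                raise ValueError(f"duplicate descriptor id {m.id}")
            meta[m.id] = m
        frames.append(frame)
    data = pd.concat(frames, axis=1)
    return DescriptorTable(data=data, meta=meta, config_hash=config_hash)
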
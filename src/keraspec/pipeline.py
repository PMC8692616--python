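"""End-to-end orchestration: simulate -> pretreat -> deconvolve -> describe
-> associate -> select -> report.

The stages are plain functions over in-memory objects; :func:`run` wires
them together under a single :class:`RunConfig` with a master seed (all
sub-seeds are derived, nothing touches global RNG state) and writes every
artifact with the config hash when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pretreat as pt
from .association import ccora, correlation_filter
from .deconv import TDFit, VoigtFit, average_fit_params, fit_td3, fit_voigt3
from .descriptors import (DescriptorConfig, DescriptorMeta, DescriptorTable,
                          assemble_table, bin_block_values, bin_log_decay,
                          default_config, derived_transforms, pca_descriptors)
from .selection import (ConsensusResult, ModelSpec, SelectionTrace, best_set,
                        consensus_topk, recursive_select)
from .spectra import Spectrum
from .synth import (PROPERTY_COLUMNS, SyntheticDataset, generate_dataset,
                    write_dataset)

logger = logging.getLogger("keraspec")

__all__ = ["RunConfig", "RunReport", "PretreatedData", "run",
           "pretreat_stage", "describe_stage", "associate_stage",
           "select_stage", "experimental_sd", "default_run_config",
           "fast_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run (hash recorded in every artifact)."""

    n_samples: int = 63
    seed: int = 0
    snr: float = 500.0
    descriptor_config: DescriptorConfig = field(default_factory=default_config)
    repeats: int = 100
    k: int = 10
    retention: float = 0.9
    consensus_k: int = 20
    rf: ModelSpec = field(default_factory=lambda: ModelSpec(algo="rf"))
    plsr: ModelSpec = field(default_factory=lambda: ModelSpec(algo="plsr"))
    properties: tuple[str, ...] = PROPERTY_COLUMNS
    voigt_starts: int = 8
    td_starts: int = 8

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["descriptor_config"] = self.descriptor_config.hash()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_run_config(seed: int = 0) -> RunConfig:
    """The reference configuration: 100x10-fold CV, 1000-tree forests with
    held-out permutation importance."""
    return RunConfig(seed=seed, rf=ModelSpec(algo="rf", seed=seed),
                     plsr=ModelSpec(algo="plsr", seed=seed))


def fast_run_config(seed: int = 0) -> RunConfig:
    """Reduced-compute configuration for interactive use and the test
    suite: 10 CV repeats, 15-tree forests with impurity importance
    (mtry = p/3 as in the reference workflow), PLSR capped at 10 latent
    variables with a 5-fold inner CV, and fewer deconvolution multi-starts.
    Study conditions (sample count, descriptor layout, noise) are
    unchanged."""
    return RunConfig(
        seed=seed, repeats=10,
        rf=ModelSpec(algo="rf", n_trees=15, max_features=1.0 / 3.0,
                     importance="impurity", seed=seed),
        plsr=ModelSpec(algo="plsr", max_components=10, inner_cv_folds=5,
                       seed=seed),
        voigt_starts=2, td_starts=2)


# ---------------------------------------------------------------------------
# pretreat + deconvolution stage
# ---------------------------------------------------------------------------

@dataclass
class PretreatedData:
    """Per-sample processed profiles, as samples x axis-point frames keyed
    by bin-block name, plus deconvolution fits per sample."""

    profiles: dict[str, pd.DataFrame]
    td_decays: pd.DataFrame          # normalized replicate-averaged decays
    td_fit_curves: pd.DataFrame      # fitted model curves on the same grid
    voigt_fits: dict[str, VoigtFit]
    td_fits: dict[str, TDFit]
    sample_ids: list[str]


def _group_spectra(spectra: list[Spectrum]) -> dict:
    grouped: dict[str, dict[str, list[Spectrum]]] = {}
    for sp in spectra:
        grouped.setdefault(sp.modality, {}).setdefault(sp.sample_id,
                                                       []).append(sp)
    return grouped


def _aligned_average(reps: list[Spectrum]) -> Spectrum:
    reps = [sp.ascending() for sp in sorted(reps, key=lambda s: s.replicate)]
    first = reps[0]
    aligned = [first]
    for sp in reps[1:]:
        if sp.axis.shape == first.axis.shape and np.allclose(
                sp.axis, first.axis, rtol=0.0, atol=1e-9):
            aligned.append(sp)
        else:
            aligned.append(pt.interpolate_to_axis(sp, first.axis))
    return pt.average_replicates(aligned)


def _sub_seed(master: int, *salt: int) -> int:
    return int(np.random.SeedSequence([master, *salt]).generate_state(1)[0]
               % (2 ** 31))


def pretreat_stage(dataset: SyntheticDataset,
                   config: RunConfig) -> PretreatedData:
    """Apply the per-modality recipes and the curve deconvolutions.

    NMR/FT-IR: differentiate -> truncate/exclude -> normalize (FT-IR
    replicates are processed individually and then averaged); DTG:
    1 degC bin -> weight-normalize -> differentiate; TD-NMR: per-replicate
    3-component fit, amplitude normalization, then replicate averaging of
    both curves and fit parameters.
    """
    dcfg = config.descriptor_config
    grouped = _group_spectra(dataset.spectra)
    sample_ids = sorted({lat.sample_id for lat in dataset.latents})
    profiles: dict[str, dict[str, pd.Series]] = {}

    def put(block: str, sid: str, sp: Spectrum) -> None:
        profiles.setdefault(block, {})[sid] = pd.Series(sp.intensity,
                                                        index=sp.axis)

    voigt_fits: dict[str, VoigtFit] = {}
    for modality, block0, block2 in (("h1_wideline", "wl", "wl.2der"),
                                     ("h1_mas", "mas", "mas.2der"),
                                     ("c13_cpmas", "cpmas", "cpmas.2der")):
        lo, hi = pt.TRUNCATION_WINDOWS[modality]
        for s_idx, sid in enumerate(sample_ids):
            avg = _aligned_average(grouped[modality][sid])
            nonder = pt.normalize_total_area(pt.truncate(avg, lo, hi))
            der = pt.normalize_total_area(
                pt.truncate(pt.sg_second_derivative(
                    avg, dcfg.window_for(modality)), lo, hi))
            put(block0, sid, nonder)
            put(block2, sid, der)
            if modality == "h1_wideline":
                voigt_fits[sid] = fit_voigt3(
                    nonder, seed=_sub_seed(config.seed, 1, s_idx),
                    n_starts=config.voigt_starts)
    for sid in sample_ids:
        reps = []
        for sp in grouped["ftir"][sid]:
            der = pt.exclude_regions(
                pt.sg_second_derivative(sp, dcfg.window_for("ftir")),
                                     pt.FTIR_EXCLUDED_REGIONS)
            reps.append(pt.normalize_total_area(der))
        put("ftir.2der", sid, _aligned_average(reps))
    for sid in sample_ids:
        prepared = [pt.dtg_prepare(sp) for sp in grouped["dtg"][sid]]
        avg = _aligned_average(prepared) if len(prepared) > 1 else prepared[0]
        put("dtg", sid, avg)
        put("dtg.2der", sid,
            pt.sg_second_derivative(avg, dcfg.window_for("dtg")))

    td_fits: dict[str, TDFit] = {}
    td_rows, fit_rows = {}, {}
    for s_idx, sid in enumerate(sample_ids):
        reps = sorted(grouped["tdnmr"][sid], key=lambda s: s.replicate)
        fits = [fit_td3(sp, seed=_sub_seed(config.seed, 2, s_idx, r),
                        n_starts=config.td_starts)
                for r, sp in enumerate(reps)]
        normalized = [pt.td_normalize(sp, fit)
                      for sp, fit in zip(reps, fits)]
        avg = pt.average_replicates(normalized)
        sample_fit = average_fit_params(fits)
        td_fits[sid] = sample_fit
        td_rows[sid] = pd.Series(avg.intensity, index=avg.axis)
        unit_fit = dataclasses.replace(sample_fit, total_amplitude=1.0)
        fit_rows[sid] = pd.Series(unit_fit.evaluate(avg.axis),
                                  index=avg.axis)

    frames = {}
    for block, rows in profiles.items():
        frame = pd.DataFrame({sid: rows[sid] for sid in sample_ids}).T
        if frame.isna().any().any():
            raise ValueError(f"inconsistent axes across samples in {block}")
        frames[block] = frame
    return PretreatedData(
        profiles=frames,
        td_decays=pd.DataFrame({s: td_rows[s] for s in sample_ids}).T,
        td_fit_curves=pd.DataFrame({s: fit_rows[s] for s in sample_ids}).T,
        voigt_fits=voigt_fits, td_fits=td_fits, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# descriptor stage
# ---------------------------------------------------------------------------

def _profile_spectrum(block_name: str, modality: str, deriv: int,
                      row: pd.Series, sid: str) -> Spectrum:
    return Spectrum(modality=modality, axis=row.index.to_numpy(dtype=float),
                    intensity=row.to_numpy(dtype=float), sample_id=sid,
                    derivative_order=deriv, lineage=(block_name,))


def describe_stage(pre: PretreatedData, config: RunConfig) -> DescriptorTable:
    """Build the full descriptor table from pre-treated profiles."""
    dcfg = config.descriptor_config
    sample_ids = pre.sample_ids
    blocks = []

    # even-step bins
    for block in dcfg.bin_blocks:
        frame_rows, meta = [], None
        for sid in sample_ids:
            row = pre.profiles[block.name].loc[sid]
            sp = _profile_spectrum(block.name, block.modality,
                                   block.derivative, row, sid)
            values, meta = bin_block_values(sp, block)
            frame_rows.append(values)
        frame = pd.DataFrame(frame_rows, index=sample_ids,
                             columns=[m.id for m in meta])
        blocks.append((frame, meta))

    # logarithmic TD bins
    td_rows, td_meta = [], None
    for sid in sample_ids:
        row = pre.td_decays.loc[sid]
        sp = Spectrum(modality="tdnmr",
                      axis=row.index.to_numpy(dtype=float),
                      intensity=row.to_numpy(dtype=float), sample_id=sid)
        values, td_meta = bin_log_decay(sp, dcfg.td_bins, dcfg.td_t_max)
        td_rows.append(values)
    blocks.append((pd.DataFrame(td_rows, index=sample_ids,
                                columns=[m.id for m in td_meta]), td_meta))

    # PCA scores per profile block (plus raw and fitted decay curves)
    pca_inputs = {f"{b.name}.pc": (pre.profiles[b.name], b.modality,
                                   b.derivative)
                  for b in dcfg.bin_blocks}
    pca_inputs["td.pc"] = (pre.td_decays, "tdnmr", 0)
    pca_inputs["tdfit.pc"] = (pre.td_fit_curves, "tdnmr", 0)
    for name, (frame, modality, deriv) in pca_inputs.items():
        scores, meta, _ = pca_descriptors(
            frame.loc[sample_ids].to_numpy(dtype=float),
            var_threshold=dcfg.pca_var_threshold, name=name,
            modality=modality, derivative=deriv)
        blocks.append((pd.DataFrame(scores, index=sample_ids,
                                    columns=[m.id for m in meta]), meta))

    # deconvolution parameters and derived transforms
    def deconv_block(family: str, modality: str, params_of) -> None:
        raw_rows, derived_rows = [], []
        raw_meta = derived_meta = None
        for sid in sample_ids:
            params = params_of(sid)
            raw_meta = [DescriptorMeta(id=f"{family}.{p}", modality=modality,
                                       processing="deconv", formula=p)
                        for p in params]
            raw_rows.append([params[p] for p in params])
            values, derived_meta = derived_transforms(params, family,
                                                      modality=modality)
            derived_rows.append([values[m.id] for m in derived_meta])
        blocks.append((pd.DataFrame(raw_rows, index=sample_ids,
                                    columns=[m.id for m in raw_meta]),
                       raw_meta))
        blocks.append((pd.DataFrame(derived_rows, index=sample_ids,
                                    columns=[m.id for m in derived_meta]),
                       derived_meta))

    def voigt_params(sid: str) -> dict[str, float]:
        fit = pre.voigt_fits[sid]
        out = {f"a{i + 1}": float(fit.area_proportions[i]) for i in range(3)}
        out.update({f"w{i + 1}": float(fit.fwhm[i]) for i in range(3)})
        return out

    def td_params(sid: str) -> dict[str, float]:
        fit = pre.td_fits[sid]
        out = {f"p{i + 1}": c.proportion
               for i, c in enumerate(fit.components)}
        out.update({f"t{i + 1}": c.relaxation_time
                    for i, c in enumerate(fit.components)})
        return out

    deconv_block("wlv", "h1_wideline", voigt_params)
    deconv_block("tdr", "tdnmr", td_params)
    return assemble_table(blocks, sample_ids, config_hash=dcfg.hash())


# ---------------------------------------------------------------------------
# association + selection stages
# ---------------------------------------------------------------------------

def associate_stage(table: DescriptorTable, property_means: pd.DataFrame,
                    scope: str = "all", r_max: float | None = None):
    """Correlation-filter the table and run CCorA against the properties."""
    filtered = correlation_filter(table, r_max=r_max, scope=scope)
    result = ccora(filtered.data.loc[property_means.index],
                   property_means, x_names=filtered.descriptor_ids,
                   y_names=list(property_means.columns))
    return filtered, result


def select_stage(table: DescriptorTable, property_means: pd.DataFrame,
                 config: RunConfig, prop: str,
                 algo: str) -> SelectionTrace:
    spec = config.rf if algo == "rf" else config.plsr
    prop_idx = list(config.properties).index(prop)
    spec = dataclasses.replace(
        spec, seed=_sub_seed(config.seed, 3, prop_idx,
                             0 if algo == "rf" else 1))
    y = property_means.loc[table.sample_ids, prop].to_numpy(dtype=float)
    return recursive_select(spec, table.data, y, retention=config.retention,
                            k=config.k, repeats=config.repeats,
                            property_name=prop)


def experimental_sd(properties: pd.DataFrame, prop: str) -> float:
    """Square root of the mean within-sample replicate variance (n-1
    denominator); the natural noise floor of the property measurement."""
    counts = properties.groupby("sample_id")[prop].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per sample")
    variances = properties.groupby("sample_id")[prop].var(ddof=1)
    return float(np.sqrt(variances.mean()))


# ---------------------------------------------------------------------------
# run + report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Best-set accuracy per property and algorithm, plus consensus lists."""

    table: pd.DataFrame
    consensus: dict[str, ConsensusResult]
    traces: dict[tuple[str, str], SelectionTrace]
    config_hash: str

    def to_json(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "table": json.loads(self.table.to_json(orient="index")),
            "consensus": {p: {"rf_top": list(c.rf_top),
                              "plsr_top": list(c.plsr_top),
                              "common": sorted(c.common)}
                          for p, c in self.consensus.items()},
        }


def build_report(dataset: SyntheticDataset,
                 traces: dict[tuple[str, str], SelectionTrace],
                 config: RunConfig) -> RunReport:
    rows = {}
    consensus = {}
    for prop in config.properties:
        row = {"experimental_sd": experimental_sd(dataset.properties, prop)}
        for algo in ("rf", "plsr"):
            ids, result = best_set(traces[(prop, algo)])
            row[f"{algo}_n_selected"] = len(ids)
            row[f"{algo}_rmse"] = result.rmse_mean
            row[f"{algo}_rmse_sd"] = result.rmse_sd
            row[f"{algo}_r2"] = result.r2_mean
            row[f"{algo}_r2_sd"] = result.r2_sd
        rows[prop] = row
        consensus[prop] = consensus_topk(traces[(prop, "rf")],
                                         traces[(prop, "plsr")],
                                         k=config.consensus_k)
    return RunReport(table=pd.DataFrame(rows).T, consensus=consensus,
                     traces=traces, config_hash=config.hash())


def _trace_to_json(trace: SelectionTrace) -> dict:
    return {
        "property": trace.property, "algo": trace.algo,
        "retention": trace.retention, "best_index": trace.best_index,
        "steps": [{
            "ids": list(s.descriptor_ids),
            "rmse_mean": s.result.rmse_mean, "rmse_sd": s.result.rmse_sd,
            "r2_mean": s.result.r2_mean, "r2_sd": s.result.r2_sd,
            "importance": s.result.importance_mean.to_dict(),
        } for s in trace.steps],
    }


def run(config: RunConfig, outdir=None,
        dataset: SyntheticDataset | None = None) -> RunReport:
    """Execute every stage; artifacts (when ``outdir`` is given) are cached
    keyed on the config hash, so a re-run with the same config reuses them."""
    chash = config.hash()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    if dataset is None:
        dataset = generate_dataset(n_samples=config.n_samples,
                                   seed=config.seed, snr=config.snr)
    if out is not None:
        ds_dir = out / "dataset"
        if not (ds_dir / "manifest.json").exists():
            write_dataset(dataset, ds_dir)
    logger.info("simulate: %.1fs", time.time() - t0)

    t0 = time.time()
    pre = pretreat_stage(dataset, config)
    table = describe_stage(pre, config)
    logger.info("pretreat+describe: %.1fs (%d descriptors)",
                time.time() - t0, table.data.shape[1])
    property_means = dataset.property_means().loc[table.sample_ids]
    if out is not None:
        table.write_csv(out / "descriptors.csv")

    t0 = time.time()
    _, ccora_result = associate_stage(table, property_means)
    if out is not None:
        ccora_result.property_scores.to_csv(out / "ccora_properties.csv")
        ccora_result.descriptor_scores.to_csv(out / "ccora_descriptors.csv")
    logger.info("associate: %.1fs", time.time() - t0)

    traces = {}
    for prop in config.properties:
        for algo in ("rf", "plsr"):
            cache = (out / f"trace_{prop}_{algo}.json"
                     if out is not None else None)
            if cache is not None and cache.exists():
                payload = json.loads(cache.read_text())
                if payload.get("config_hash") == chash:
                    traces[(prop, algo)] = _trace_from_json(payload)
                    continue
            t0 = time.time()
            trace = select_stage(table, property_means, config, prop, algo)
            traces[(prop, algo)] = trace
            logger.info("select %s/%s: %.1fs", prop, algo, time.time() - t0)
            if cache is not None:
                payload = _trace_to_json(trace)
                payload["config_hash"] = chash
                cache.write_text(json.dumps(payload))
    report = build_report(dataset, traces, config)
    if out is not None:
        report.table.to_csv(out / "report.csv")
        (out / "report.json").write_text(json.dumps(report.to_json(),
                                                    indent=1))
    return report


def _trace_from_json(payload: dict) -> SelectionTrace:
    from .selection import CVResult, SelectionStep
    steps = []
    for s in payload["steps"]:
        imp = pd.Series(s["importance"])
        steps.append(SelectionStep(
            tuple(s["ids"]),
            CVResult(rmse_mean=s["rmse_mean"], rmse_sd=s["rmse_sd"],
                     r2_mean=s["r2_mean"], r2_sd=s["r2_sd"],
                     importance_mean=imp, n_repeats=0, k=0)))
    return SelectionTrace(steps=steps, property=payload["property"],
                          algo=payload["algo"],
                          retention=payload["retention"])
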
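"""End-to-end analysis orchestration.

``run_full_analysis`` executes the stages in a fixed order — ingest or
simulate, mean-center, trophic positions, ln-distance regressions,
assumption-gated group comparisons, PERMANOVA + LDA per feature block —
under one master seed, and collects every result into delimited-text
tables whose header lines record the seed and a configuration hash, so
a rerun with the same configuration reproduces the report byte for
byte.

Feature blocks for the multivariate stage:

* ``carbon_only`` — the 6 mean-centered d13C EAA values;
* ``carbon_nitrogen`` — plus d15N of Phe and Lys (8 features);
* ``carbon_nitrogen_tp`` — plus the two trophic-position estimates
  (10 features).

Feature assembly is complete-case: samples missing any selected
feature are dropped and logged, so different blocks may use different
sample counts.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centering import mean_center_dataset
from .datamodel import EAA_CARBON, SAA_NITROGEN, Dataset
from .exceptions import ConfigError, EmptyResultError, InsufficientDataError
from .gradients import (ALPHA, compare_groups, regression_family)
from .io import read_sample_table
from .multivariate import (FeatureMatrix, lda_classify, lda_fit,
                           loocv_accuracy, pairwise_permanova, permanova)
from .simulate import GeneratorConfig, SimulationResult, simulate_dataset
from .trophic import PRESETS, TPParameterization, batch_tp

FEATURE_BLOCKS = ("carbon_only", "carbon_nitrogen", "carbon_nitrogen_tp")


@dataclass
class AnalysisConfig:
    """Configuration for one full pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be set.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    aa_set: tuple[str, ...] = EAA_CARBON
    tp_parameterizations: tuple[str, ...] = ("GlxPhe", "AlaPhe")
    feature_blocks: tuple[str, ...] = FEATURE_BLOCKS
    n_perm: int = 999
    seed: int = 0
    alpha: float = ALPHA
    exclude_deep_for_d15n_regression: bool = True

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise ConfigError(
                "exactly one of input_path / generator must be provided")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for block in self.feature_blocks:
            if block not in FEATURE_BLOCKS:
                raise ConfigError(f"unknown feature block {block!r}")
        for name in self.tp_parameterizations:
            if name not in PRESETS:
                raise ConfigError(f"unknown TP parameterization {name!r}")

    def resolve_params(self) -> list[TPParameterization]:
        return [PRESETS[name] for name in self.tp_parameterizations]

    def to_dict(self) -> dict:
        from .simulate import config_to_dict
        return {
            "input_path": self.input_path,
            "generator": config_to_dict(self.generator) if self.generator else None,
            "aa_set": list(self.aa_set),
            "tp_parameterizations": list(self.tp_parameterizations),
            "feature_blocks": list(self.feature_blocks),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha": self.alpha,
            "exclude_deep_for_d15n_regression": self.exclude_deep_for_d15n_regression,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All tables from one run plus run metadata."""

    tables: dict[str, pd.DataFrame]
    metadata: dict
    notes: list[str] = field(default_factory=list)

    def write(self, outdir) -> list[Path]:
        """Write every table as a TSV with a metadata header line."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = ("# aacsia={version} seed={seed} config_hash={config_hash}\n"
                  .format(**self.metadata))
        written = []
        for name, frame in self.tables.items():
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=False,
                             float_format="%.10g", lineterminator="\n")
            written.append(path)
        return written

    def report_hash(self) -> str:
        """Hash of all table contents (order-stable); equal hashes mean
        byte-identical reports."""
        h = hashlib.sha256()
        for name in sorted(self.tables):
            buf = _io.StringIO()
            self.tables[name].to_csv(buf, sep="\t", index=False,
                                     float_format="%.10g", lineterminator="\n")
            h.update(name.encode())
            h.update(buf.getvalue().encode())
        return h.hexdigest()


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def assemble_features(dataset: Dataset, block: str,
                      aa_set=EAA_CARBON,
                      tp_params: list[TPParameterization] | None = None,
                      ) -> tuple[FeatureMatrix, list[str]]:
    """Build a complete-case feature matrix for one block.

    Returns ``(matrix, dropped_sample_ids)``. Labels come from each
    record's habitat; records without a habitat are dropped.
    """
    if block not in FEATURE_BLOCKS:
        raise ConfigError(f"unknown feature block {block!r}")
    aa_set = tuple(aa_set)
    tp_params = tp_params if tp_params is not None else []
    if block == "carbon_nitrogen_tp" and not tp_params:
        raise ConfigError("carbon_nitrogen_tp block needs TP parameterizations")

    names = [f"d13C_{aa}_centered" for aa in aa_set]
    if block in ("carbon_nitrogen", "carbon_nitrogen_tp"):
        names += [f"d15N_{aa}" for aa in SAA_NITROGEN]
    if block == "carbon_nitrogen_tp":
        names += [f"TP_{p.name}" for p in tp_params]

    ids, labels, rows, dropped = [], [], [], []
    for rec in dataset:
        if rec.habitat is None:
            dropped.append(rec.sample_id)
            continue
        row = []
        ok = True
        carbon = [rec.get(aa, "d13C") for aa in aa_set]
        if any(m is None for m in carbon):
            ok = False
        else:
            vals = np.array([m.value for m in carbon])
            row.extend(vals - vals.mean())
        if ok and block in ("carbon_nitrogen", "carbon_nitrogen_tp"):
            for aa in SAA_NITROGEN:
                m = rec.get(aa, "d15N")
                if m is None:
                    ok = False
                    break
                row.append(m.value)
        if ok and block == "carbon_nitrogen_tp":
            for p in tp_params:
                mt = rec.get(p.trophic_aa, "d15N")
                ms = rec.get(p.source_aa, "d15N")
                if mt is None or ms is None:
                    ok = False
                    break
                row.append(((mt.value - ms.value) - p.beta) / p.tdf + 1.0)
        if not ok:
            dropped.append(rec.sample_id)
            continue
        ids.append(rec.sample_id)
        labels.append(rec.habitat)
        rows.append(row)
    if not ids:
        raise EmptyResultError(f"no complete-case sample for block {block!r}")
    return FeatureMatrix(ids, names, np.array(rows), labels), dropped


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute every enabled stage and assemble the report.

    Statistical non-significance is a result, not an error; only data-
    contract failures abort, naming the stage.
    """
    notes: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    # -- stage: input ------------------------------------------------------
    if config.generator is not None:
        sim: SimulationResult = simulate_dataset(config.generator)
        dataset = sim.dataset
        tables["truth"] = sim.truth
    else:
        dataset = read_sample_table(config.input_path)
        for rec in dataset:
            if rec.habitat is None and rec.distance_km is not None:
                rec.assign_habitat_from_metadata()
    dataset.require_nonempty("run_full_analysis")
    params = config.resolve_params()

    # -- stage: mean-centering --------------------------------------------
    profiles, skipped = mean_center_dataset(dataset, config.aa_set)
    for sid, reason in skipped:
        notes.append(f"centering: skipped {sid}: {reason}")
    prof_by_id = {p.sample_id: p for p in profiles}
    tables["centered_profiles"] = pd.DataFrame(
        [{"sample_id": p.sample_id, "amino_acid": aa,
          "centered_d13C": p.centered_values[aa],
          "sample_mean_d13C": p.sample_mean}
         for p in profiles for aa in p.aa_set])

    # -- stage: trophic positions -----------------------------------------
    tp_frames = {}
    for p in params:
        try:
            estimates, tp_skipped = batch_tp(dataset, p)
        except EmptyResultError as exc:
            raise EmptyResultError(f"trophic_position stage: {exc}") from None
        for sid, reason in tp_skipped:
            notes.append(f"tp[{p.name}]: skipped {sid}: {reason}")
        tp_frames[p.name] = pd.DataFrame(
            [{"sample_id": e.sample_id, "parameterization": e.parameterization,
              "tp": e.tp, "tp_sd": e.tp_sd} for e in estimates])
        tables[f"tp_{p.name}"] = tp_frames[p.name]

    meta = {r.sample_id: r for r in dataset}

    def _with_distance(series: dict[str, float]):
        pairs = [(v, meta[sid].distance_km) for sid, v in series.items()
                 if meta[sid].distance_km is not None]
        return ([v for v, _ in pairs], [d for _, d in pairs])

    # -- stage: ln-distance regressions -----------------------------------
    fam_values, fam_dist = {}, {}
    for aa in config.aa_set:
        series = {sid: prof.centered_values[aa]
                  for sid, prof in prof_by_id.items()}
        vals, dists = _with_distance(series)
        if len(vals) >= 3:
            fam_values[f"d13C_{aa}_centered"] = vals
            fam_dist[f"d13C_{aa}_centered"] = dists
    if fam_values:
        tables["regressions_d13c"] = _regression_table(fam_values, fam_dist)

    fam_values, fam_dist = {}, {}
    for aa in SAA_NITROGEN:
        series = {}
        for rec in dataset:
            if config.exclude_deep_for_d15n_regression and rec.habitat == "offshore_deep":
                continue
            m = rec.get(aa, "d15N")
            if m is not None:
                series[rec.sample_id] = m.value
        vals, dists = _with_distance(series)
        if len(vals) >= 3:
            fam_values[f"d15N_{aa}"] = vals
            fam_dist[f"d15N_{aa}"] = dists
    if fam_values:
        tables["regressions_d15n"] = _regression_table(fam_values, fam_dist)

    fam_values, fam_dist = {}, {}
    for p in params:
        series = dict(zip(tp_frames[p.name]["sample_id"], tp_frames[p.name]["tp"]))
        vals, dists = _with_distance(series)
        if len(vals) >= 3:
            fam_values[f"TP_{p.name}"] = vals
            fam_dist[f"TP_{p.name}"] = dists
    if fam_values:
        tables["regressions_tp"] = _regression_table(fam_values, fam_dist)

    # -- stage: group comparisons -----------------------------------------
    omnibus_rows, pairwise_rows = [], []

    def _compare(name: str, series: dict[str, float]):
        pairs = [(v, meta[sid].habitat) for sid, v in series.items()
                 if meta[sid].habitat is not None]
        labels = [lab for _, lab in pairs]
        if len(set(labels)) != 3:
            notes.append(f"group test {name}: needs 3 habitats, "
                         f"found {sorted(set(labels))}; skipped")
            return
        try:
            res = compare_groups([v for v, _ in pairs], labels, response=name)
        except InsufficientDataError as exc:
            notes.append(f"group test {name}: {exc}; skipped")
            return
        omnibus_rows.append({
            "response": name, "path": res.path,
            "omnibus_stat": res.omnibus_stat, "omnibus_p": res.omnibus_p,
            "levene_p": res.gate_report.get("levene_p"),
        })
        for (ga, gb), p_adj in res.pairwise:
            pairwise_rows.append({"response": name, "group_a": ga,
                                  "group_b": gb, "p_adj": p_adj})

    for aa in config.aa_set:
        _compare(f"d13C_{aa}_centered",
                 {sid: prof.centered_values[aa]
                  for sid, prof in prof_by_id.items()})
    for aa in SAA_NITROGEN:
        _compare(f"d15N_{aa}",
                 {rec.sample_id: rec.value(aa, "d15N")
                  for rec in dataset if rec.has(aa, "d15N")})
    for p in params:
        _compare(f"TP_{p.name}",
                 dict(zip(tp_frames[p.name]["sample_id"],
                          tp_frames[p.name]["tp"])))
    if omnibus_rows:
        tables["group_tests"] = pd.DataFrame(omnibus_rows)
    if pairwise_rows:
        tables["group_tests_pairwise"] = pd.DataFrame(pairwise_rows)

    # -- stage: multivariate ----------------------------------------------
    perm_rows, perm_pair_rows = [], []
    score_rows, loading_rows, lda_rows = [], [], []
    for block in config.feature_blocks:
        try:
            features, dropped = assemble_features(
                dataset, block, config.aa_set, params)
        except EmptyResultError as exc:
            raise EmptyResultError(f"multivariate stage [{block}]: {exc}") from None
        for sid in dropped:
            notes.append(f"block {block}: dropped {sid} (incomplete features)")
        n_groups = len(features.groups())
        seed = stage_seed(config.seed, f"permanova:{block}")
        res = permanova(features, n_perm=config.n_perm, seed=seed)
        perm_rows.append({
            "block": block, "n": features.n, "pseudo_f": res.pseudo_f,
            "r2": res.r2, "p": res.p, "dispersion_p": res.dispersion_p,
            "n_perm": res.n_perm, "exhaustive": res.exhaustive, "seed": seed,
        })
        if n_groups >= 3 and res.p < config.alpha:
            for c in pairwise_permanova(features, n_perm=config.n_perm,
                                        seed=stage_seed(config.seed,
                                                        f"pairwise:{block}")):
                perm_pair_rows.append({
                    "block": block, "group_a": c.pair[0], "group_b": c.pair[1],
                    "pseudo_f": c.pseudo_f, "p_raw": c.p_raw, "p_adj": c.p_adj})
        elif n_groups >= 3:
            notes.append(f"block {block}: omnibus PERMANOVA p={res.p:.4g} "
                         f">= alpha; pairwise contrasts suppressed")

        model = lda_fit(features)
        labels, post = lda_classify(model, features)
        coords = model.transform(features.values)
        acc = loocv_accuracy(features)
        lda_rows.append({
            "block": block, "n": features.n, "loocv_accuracy": acc,
            **{f"var_prop_LD{j + 1}": model.variance_proportions[j]
               for j in range(len(model.variance_proportions))}})
        for i, sid in enumerate(features.sample_ids):
            row = {"block": block, "sample_id": sid,
                   "habitat": features.labels[i], "predicted": labels[i]}
            for j in range(coords.shape[1]):
                row[f"LD{j + 1}"] = coords[i, j]
            for ci, cls in enumerate(model.classes):
                row[f"posterior_{cls}"] = post[i, ci]
            score_rows.append(row)
        for j in range(model.axes.shape[1]):
            for fi, fname in enumerate(model.feature_names):
                loading_rows.append({"block": block, "axis": f"LD{j + 1}",
                                     "feature": fname,
                                     "loading": model.axes[fi, j]})
    tables["permanova"] = pd.DataFrame(perm_rows)
    if perm_pair_rows:
        tables["permanova_pairwise"] = pd.DataFrame(perm_pair_rows)
    tables["lda_summary"] = pd.DataFrame(lda_rows)
    tables["lda_scores"] = pd.DataFrame(score_rows)
    tables["lda_loadings"] = pd.DataFrame(loading_rows)

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    return AnalysisReport(tables=tables, metadata=metadata, notes=notes)


def _regression_table(fam_values: dict, fam_dist: dict) -> pd.DataFrame:
    fits = regression_family(fam_values, fam_dist)
    return pd.DataFrame(
        [{"response": f.response, "slope": f.slope, "intercept": f.intercept,
          "adj_r2": f.adj_r2, "p_raw": f.p_raw, "p_adj": f.p_adj, "n": f.n}
         for f in fits])
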
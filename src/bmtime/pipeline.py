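"""End-to-end orchestration: select -> filter -> normalise -> DEG -> ORA -> BMT.

Per compound the pipeline selects treated and time-matched vehicle samples,
applies the row-sum low-count filter, normalises, runs per-time-point NB Wald
differential expression, runs over-representation analysis at the peak-DEG
time point, and feeds the Williams-prefiltered probes into the benchmark-time
engine.  All intermediate tables are written as TSV and a JSON run report
collects the headline numbers; identical config + seed gives identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import bmt as bmt_mod
from . import deg as deg_mod
from . import io as io_mod
from . import models, ora, synth

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """All pipeline cut-offs; defaults are the study's stated values."""

    row_sum: int = 100
    deg_alpha: float = 0.01
    deg_lfc: float = 1.0
    ora_min_overlap: int = 5
    ora_p: float = 0.01
    ora_q: float = 0.05
    williams_alpha: float = 0.05
    williams_lfc: float = 1.0
    bmt_ratio_max: float = 40.0
    fit_p_min: float = 0.1
    t_min: float = 0.1
    t_max: float = 24.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class PipelineConfig:
    counts: str | Path = "counts.tsv"
    metadata: str | Path = "metadata.tsv"
    gmt: str | Path = "pathways.gmt"
    outdir: str | Path = "bmtime_out"
    compounds: list[str] | None = None  # None = every non-vehicle compound
    vehicle_label: str = "DMSO"
    thresholds: Thresholds = field(default_factory=Thresholds)
    bmr: str = bmt_mod.DEFAULT_BMR_SPEC
    n_perm: int = 1000
    n_boot: int = 250
    ora_all_time_points: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path, **kw):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(config: PipelineConfig, counts: pd.DataFrame | None = None,
                 metadata: pd.DataFrame | None = None,
                 collection: io_mod.GeneSetCollection | None = None) -> dict:
    """Run every stage for every compound; returns the run report dict.

    In-memory inputs may be passed to skip re-reading the paths in ``config``.
    """
    thr = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if counts is None:
            counts = io_mod.read_counts(config.counts)
        if metadata is None:
            metadata = io_mod.read_metadata(config.metadata)
        if collection is None:
            collection = io_mod.read_gmt(config.gmt)
    except Exception as e:  # noqa: BLE001
        raise StageError("input", str(e)) from e

    compounds = config.compounds
    if compounds is None:
        compounds = sorted(set(metadata.loc[~metadata["is_vehicle"], "compound"]))
    missing = set(compounds) - set(metadata["compound"])
    if missing:
        raise StageError("select", f"unknown compounds: {sorted(missing)}")

    report: dict = {
        "config": _config_echo(config),
        "compounds": {},
    }
    for compound in compounds:
        report["compounds"][compound] = _run_compound(
            compound, counts, metadata, collection, config, outdir / compound)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default) + "\n")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["counts"], d["metadata"] = str(d["counts"]), str(d["metadata"])
    d["gmt"], d["outdir"] = str(d["gmt"]), str(d["outdir"])
    return d


def _run_compound(compound, counts, metadata, collection,
                  config: PipelineConfig, outdir: Path) -> dict:
    thr = config.thresholds
    # stable per-compound sub-seed (zlib.crc32 is deterministic across runs,
    # unlike hash() on strings)
    seed = int(np.random.SeedSequence(
        [config.seed, zlib.crc32(compound.encode())]).generate_state(1)[0] % (2**31))

    try:
        treated_md, control_md = io_mod.select_samples(metadata, compound)
        cols = list(treated_md["sample_id"]) + list(control_md["sample_id"])
        filtered = io_mod.filter_low_counts(counts, cols, threshold=thr.row_sum)
        if filtered.empty:
            raise ValueError("no probes survive the row-sum filter")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", f"{compound}: {e}") from e

    try:
        sf = deg_mod.size_factors(filtered[cols])
        md_all = pd.concat([treated_md, control_md])
        groups = [f"{c}:{t}" for c, t in zip(md_all["compound"], md_all["time_h"])]
        disp = deg_mod.estimate_dispersions(filtered[cols], sf, groups)
        tables, sig_counts, peak_time = deg_mod.deg_time_series(
            filtered, metadata, compound, sf=sf, dispersions=disp,
            alpha=thr.deg_alpha, lfc_threshold=thr.deg_lfc)
    except Exception as e:  # noqa: BLE001
        raise StageError("deg", f"{compound}: {e}") from e
    for t, tab in tables.items():
        _write(tab, outdir / f"deg_t{t:g}h.tsv")

    background = sorted({io_mod.probe_to_gene(p) for p in filtered.index})
    try:
        ora_times = sorted(tables) if config.ora_all_time_points else [peak_time]
        ora_tables = {}
        for t in ora_times:
            tab = tables[t]
            sig_genes = sorted(set(tab.loc[tab["significant"], "gene"]))
            ora_tables[t] = ora.run_ora(
                sig_genes, collection, background,
                min_overlap=thr.ora_min_overlap, p_threshold=thr.ora_p,
                q_threshold=thr.ora_q)
            _write(ora_tables[t], outdir / f"ora_t{t:g}h.tsv")
        ora_peak = ora_tables[peak_time]
    except Exception as e:  # noqa: BLE001
        raise StageError("ora", f"{compound}: {e}") from e

    try:
        responses = bmt_mod.build_time_response(filtered, metadata, compound, sf=sf)
        pref = bmt_mod.prefilter(responses, alpha=thr.williams_alpha,
                                 lfc_threshold=thr.williams_lfc,
                                 n_perm=config.n_perm, seed=seed)
        _write(pref, outdir / "williams_prefilter.tsv")
        eligible = pref.index[pref["eligible"]].tolist()
        bmt_table = bmt_mod.bmt_analysis(
            responses, eligible, bmr_spec=config.bmr, n_boot=config.n_boot,
            seed=seed + 1, t_min=thr.t_min, t_max=thr.t_max,
            ratio_max=thr.bmt_ratio_max, fit_p_min=thr.fit_p_min)
        _write(bmt_table, outdir / "bmt.tsv")
        retained = bmt_table[bmt_table["retained"]]
        acc = bmt_mod.accumulation_curve(retained["BMT"])
        _write(acc, outdir / "bmt_accumulation.tsv", index=False)
        earliest = bmt_mod.earliest_response_genes(
            tables, alpha=thr.deg_alpha, lfc_threshold=thr.deg_lfc)
        _write(earliest, outdir / "earliest_genes.tsv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("bmt", f"{compound}: {e}") from e

    sig_sets = ora_peak.index[ora_peak["significant"]].tolist()
    return {
        "probes_after_filter": int(filtered.shape[0]),
        "significant_degs_per_time": {f"{t:g}": int(c)
                                      for t, c in sig_counts.items()},
        "peak_time_h": peak_time,
        "significant_ora_sets_at_peak": sig_sets,
        "probes_eligible_for_bmt": int(len(eligible)),
        "retained_bmt_count": int(retained.shape[0]),
        "earliest_genes": earliest.head(20).to_dict(orient="records"),
    }


# ---------------------------------------------------------------------------
# simulation harness
# ---------------------------------------------------------------------------

def simulate_and_run(sim_config: synth.SimulationConfig,
                     pipeline_config: PipelineConfig | None = None,
                     workdir: str | Path = "bmtime_sim") -> tuple[dict, dict]:
    """Simulate an experiment, run the pipeline on it, and score recovery.

    Returns (report, recovery) where recovery joins pipeline output to the
    simulation ground truth: DEG sensitivity and false-discovery proportion,
    top-ORA-set correctness per active compound, the distribution of relative
    BMT errors against the analytic truth (inverted at each probe's resolved
    BMR, so estimate and truth share a benchmark-response definition), and the
    rank correlation of earliest-gene ordering against planted onsets.
    """
    workdir = Path(workdir)
    counts, metadata, truth = synth.simulate_experiment(sim_config)
    collection = synth.pathway_gene_sets(truth)
    if pipeline_config is None:
        pipeline_config = PipelineConfig(seed=sim_config.seed)
    pipeline_config.outdir = workdir
    pipeline_config.vehicle_label = sim_config.vehicle_label
    report = run_pipeline(pipeline_config, counts=counts, metadata=metadata,
                          collection=collection)

    recovery: dict = {"compounds": {}}
    rel_errors_all, rank_rhos = [], []
    for compound, cres in report["compounds"].items():
        tr_truth = truth[truth["compound"] == compound].set_index("probe")
        outdir = workdir / compound

        # DEG recovery: union of significant probes over time vs responder flag
        sig_probes: set[str] = set()
        for t in cres["significant_degs_per_time"]:
            tab = pd.read_csv(outdir / f"deg_t{t}h.tsv", sep="\t", index_col=0)
            sig_probes |= set(tab.index[tab["significant"]])
        responders = set(tr_truth.index[tr_truth["responder"]])
        tested = set(pd.read_csv(outdir / "bmt.tsv", sep="\t")["probe"]) | sig_probes
        tp = len(sig_probes & responders)
        sens = tp / len(responders) if responders else float("nan")
        fdp = (len(sig_probes - responders) / len(sig_probes)) if sig_probes else 0.0

        # BMT recovery at matched per-probe BMR
        bmt_tab = pd.read_csv(outdir / "bmt.tsv", sep="\t", index_col=0)
        rel_errors = []
        for probe, row in bmt_tab[bmt_tab["retained"]].iterrows():
            if probe not in tr_truth.index or not tr_truth.loc[probe, "responder"]:
                continue
            fam = tr_truth.loc[probe, "family"]
            theta = json.loads(tr_truth.loc[probe, "theta"])
            t_true = synth.true_bmt(fam, theta, float(row["bmr"]), t_max=240.0)
            if t_true is None or t_true <= 0:
                continue
            rel_errors.append(abs(row["BMT"] - t_true) / t_true)
        rel_errors_all.extend(rel_errors)

        # earliest-gene ordering vs planted onset order (truth BMT as onset proxy)
        earliest = pd.read_csv(outdir / "earliest_genes.tsv", sep="\t")
        rho = float("nan")
        if len(earliest) >= 3:
            onset = (tr_truth[tr_truth["responder"]]
                     .groupby("gene")["true_bmt"].min())
            joined = earliest.join(onset.rename("true_onset"), on="gene").dropna()
            if len(joined) >= 3 and joined["first_time_h"].nunique() > 1:
                rho = float(sstats.spearmanr(joined["first_time_h"],
                                             joined["true_onset"]).statistic)
        if np.isfinite(rho):
            rank_rhos.append(rho)

        planted = sorted(set(tr_truth.loc[tr_truth["responder"], "pathway"]))
        top_set = cres["significant_ora_sets_at_peak"][:1]
        recovery["compounds"][compound] = {
            "deg_sensitivity": sens,
            "deg_false_discovery_proportion": fdp,
            "n_significant_probes": len(sig_probes),
            "planted_pathways": planted,
            "top_ora_set": top_set[0] if top_set else None,
            "top_ora_in_planted": bool(top_set and top_set[0] in planted),
            "bmt_median_rel_error": (float(np.median(rel_errors))
                                     if rel_errors else float("nan")),
            "n_bmt_scored": len(rel_errors),
            "earliest_rank_rho": rho,
        }

    recovery["bmt_median_rel_error"] = (float(np.median(rel_errors_all))
                                        if rel_errors_all else float("nan"))
    recovery["n_bmt_scored"] = len(rel_errors_all)
    recovery["earliest_rank_rho_mean"] = (float(np.mean(rank_rhos))
                                          if rank_rhos else float("nan"))
    (workdir / "recovery.json").write_text(
        json.dumps(recovery, indent=2, sort_keys=True, default=_json_default) + "\n")
    return report, recovery
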
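"""Synthetic targeted-panel time-course experiments with known ground truth.

Emulates a TempO-Seq-style design: a fixed probe panel (~3,565 probes, probe
IDs ``GENE_probeid``), a 1-24 h time grid (default 1, 2, 4, 6, 8, 12, 16, 20,
24 h), three biological replicates per condition per time point, matched
vehicle controls at every time point, and negative-binomial counts.

Responder probes belong to named stress-response pathways (disjoint sets) and
follow a planted log2 fold-change trajectory drawn from one of the parametric
time-response families; an inert negative-control archetype plants nothing.
The planted trajectory for a probe with family f and parameters theta is the
baseline-anchored curve

    delta(t) = f(t; theta) - f(0; theta),

so every responder departs from zero at t = 0 and its analytic benchmark time
(smallest t with |delta(t)| = BMR) is available as an oracle for recovery
tests.

Counts for sample j and probe g are NB with mean s_j * q_g * 2**(delta_g(t_j))
for treated samples (delta == 0 for vehicle), library-size factor s_j
log-normal, baseline expression q_g log-uniform over ~3 orders of magnitude,
and per-probe dispersion drawn log-normally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .io import GeneSetCollection, write_counts, write_gmt, write_metadata

DEFAULT_TIME_POINTS = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0, 24.0)

#: families used for planting responses (all are valid fit families)
PLANT_FAMILIES = ("Linear", "Power", "Hill", "Exp4", "Exp5")


@dataclass
class PathwayResponse:
    """How one compound activates one pathway's responder genes.

    amplitude is the plateau |log2FC| (per-gene jitter applied around it),
    onset_h the characteristic activation time in hours, shape the steepness
    exponent of the family, and frac_down the fraction of responder genes in
    this pathway that are down- rather than up-regulated.
    """

    family: str = "Hill"
    amplitude: float = 3.0
    onset_h: float = 6.0
    shape: float = 3.0
    frac_down: float = 0.25

    def __post_init__(self):
        if self.family not in PLANT_FAMILIES:
            raise ValueError(f"unsupported planted family {self.family!r}")
        if self.amplitude <= 0 or self.onset_h <= 0:
            raise ValueError("amplitude and onset_h must be positive")


@dataclass
class CompoundArchetype:
    """A simulated compound: a response spec per pathway, or inert."""

    name: str
    concentration: float = 1.0
    inert: bool = False
    responses: dict[str, PathwayResponse] = field(default_factory=dict)

    def __post_init__(self):
        if self.inert and self.responses:
            raise ValueError("inert archetype must plant no responses")


def default_compounds() -> list[CompoundArchetype]:
    """Four active archetypes with staggered pathway onsets plus one inert control.

    The onset ordering (metal stress early, oxidative stress mid, unfolded
    protein response late for the first archetype, and so on) gives downstream
    earliest-response-gene and accumulation analyses a known sequential
    activation pattern to recover.
    """
    return [
        CompoundArchetype("metalotox", concentration=10.0, responses={
            "metal_stress": PathwayResponse("Hill", amplitude=3.5, onset_h=3.0, shape=3.0),
            "oxidative_stress": PathwayResponse("Hill", amplitude=3.0, onset_h=6.0, shape=3.0),
            "unfolded_protein": PathwayResponse("Exp5", amplitude=1.8, onset_h=12.0, shape=2.0),
        }),
        CompoundArchetype("proteotox", concentration=0.3, responses={
            "unfolded_protein": PathwayResponse("Exp5", amplitude=3.5, onset_h=8.0, shape=2.0),
            "oxidative_stress": PathwayResponse("Hill", amplitude=1.6, onset_h=14.0, shape=4.0),
        }),
        CompoundArchetype("mitotox", concentration=0.005, responses={
            "unfolded_protein": PathwayResponse("Exp4", amplitude=2.2, onset_h=12.0),
            "oxidative_stress": PathwayResponse("Power", amplitude=2.0, onset_h=12.0,
                                                shape=2.0, frac_down=0.5),
        }),
        CompoundArchetype("mixotox", concentration=50.0, responses={
            "metal_stress": PathwayResponse("Hill", amplitude=1.8, onset_h=6.0, shape=3.0),
            "unfolded_protein": PathwayResponse("Exp4", amplitude=1.9, onset_h=14.0),
        }),
        CompoundArchetype("inert_control", concentration=1.0, inert=True),
    ]


@dataclass
class SimulationConfig:
    """Design and noise model of one simulated experiment.

    Defaults mirror the targeted-panel study design this package emulates:
    3,565 probes, nine time points from 1 to 24 h, three replicates, matched
    vehicle controls.  library_size_cv and the dispersion log-normal are
    assumptions (the real control-sample depth distribution is not published)
    and are exposed here for that reason.
    """

    n_probes: int = 3565
    pathway_sizes: dict[str, int] = field(default_factory=lambda: {
        "metal_stress": 40, "oxidative_stress": 40, "unfolded_protein": 40})
    compounds: list[CompoundArchetype] = field(default_factory=default_compounds)
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    library_size_mean: float = 1.0
    library_size_cv: float = 0.25
    dispersion_log_mean: float = float(np.log(0.05))
    dispersion_log_sd: float = 0.6
    baseline_range: tuple[float, float] = (0.5, 500.0)
    responder_baseline_range: tuple[float, float] = (20.0, 500.0)
    min_amplitude: float = 1.2
    frac_multiprobe_genes: float = 0.05
    truth_bmr: float = 1.0
    vehicle_label: str = "DMSO"
    seed: int = 0

    def __post_init__(self):
        tp = tuple(float(t) for t in self.time_points_h)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points_h must be strictly increasing and positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if sum(self.pathway_sizes.values()) > self.n_probes:
            raise ValueError("responder sets exceed the probe panel")


def true_bmt(family: str, theta, bmr: float, t_max: float = 100.0):
    """Analytic benchmark time of a planted curve: smallest t > 0 with
    |f(t) - f(0)| = bmr; closed form for Linear/Power/Hill, bisection otherwise;
    None if the change never reaches bmr on (0, t_max]."""
    return models.benchmark_time(family, theta, bmr, t_max=t_max)


def truth_curve(family: str, theta):
    """The planted log2FC trajectory delta(t) = f(t) - f(0) as a callable."""
    theta = np.asarray(theta, float)
    f0 = float(models.curve(family, theta, 0.0))

    def delta(t):
        return models.curve(family, theta, t) - f0

    return delta


def _draw_theta(spec: PathwayResponse, rng: np.random.Generator,
                min_amplitude: float) -> tuple[np.ndarray, int]:
    """Per-gene parameter jitter around the archetype's pathway response."""
    amp = max(spec.amplitude * rng.lognormal(0.0, 0.2), min_amplitude)
    onset = spec.onset_h * rng.uniform(0.75, 1.35)
    shape = max(spec.shape * rng.uniform(0.8, 1.25), 1.0)
    sign = -1 if rng.random() < spec.frac_down else 1
    if spec.family == "Linear":
        theta = np.array([0.0, sign * amp / 24.0])
    elif spec.family == "Power":
        shape = min(shape, models.SHAPE_MAX)
        theta = np.array([0.0, sign * amp / 24.0 ** shape, shape])
    elif spec.family == "Hill":
        shape = min(shape, models.SHAPE_MAX)
        theta = np.array([0.0, sign * amp, onset, shape])
    elif spec.family == "Exp4":
        theta = np.array([0.0, sign * amp, np.log(2.0) / onset])
    elif spec.family == "Exp5":
        shape = min(shape, models.SHAPE_MAX)
        theta = np.array([0.0, sign * amp, np.log(2.0) ** (1.0 / shape) / onset, shape])
    else:  # pragma: no cover - guarded by PathwayResponse
        raise ValueError(spec.family)
    return theta, sign


def _build_panel(config: SimulationConfig, rng: np.random.Generator):
    """Probe IDs, gene symbols, and the pathway assignment of the panel."""
    n = config.n_probes
    n_extra = int(round(config.frac_multiprobe_genes * n))
    n_genes = n - n_extra
    genes = [f"G{i:04d}" for i in range(n_genes)]
    gene_of_probe = list(genes)
    # a fraction of genes carry a second probe, as targeted panels do
    dup = rng.choice(n_genes, size=n_extra, replace=False)
    gene_of_probe += [genes[i] for i in dup]
    probes = []
    seen: dict[str, int] = {}
    for g in gene_of_probe:
        k = seen.get(g, 0)
        probes.append(f"{g}_{10000 + 7 * int(g[1:]) + k}")
        seen[g] = k + 1
    order = rng.permutation(n)
    probes = [probes[i] for i in order]
    gene_of_probe = [gene_of_probe[i] for i in order]

    # disjoint responder sets assigned at the *gene* level so that multi-probe
    # genes never straddle two pathways
    pathway_of_gene: dict[str, str] = {}
    gene_pool = list(dict.fromkeys(gene_of_probe))
    rng.shuffle(gene_pool)
    cursor = 0
    for pw, size in config.pathway_sizes.items():
        for g in gene_pool[cursor:cursor + size]:
            pathway_of_gene[g] = pw
        cursor += size
    pathway = [pathway_of_gene.get(g, "background") for g in gene_of_probe]
    return probes, gene_of_probe, pathway


def simulate_experiment(config: SimulationConfig):
    """Simulate counts, metadata, and ground truth for one experiment.

    Returns (counts, metadata, truth):

    * counts — probes x samples integer DataFrame (one matched vehicle series
      shared across compounds, as a single untreated control arm);
    * metadata — one row per sample (sample_id, compound, concentration,
      time_h, replicate, is_vehicle);
    * truth — one row per (compound, probe): responder flag, pathway, planted
      family, parameters (JSON), direction, and analytic benchmark time at
      ``config.truth_bmr`` log2 units.
    """
    rng = np.random.default_rng(config.seed)
    probes, genes, pathway = _build_panel(config, rng)
    n = config.n_probes
    times = np.asarray(config.time_points_h, float)
    reps = config.n_replicates

    lo, hi = config.baseline_range
    q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    is_responder_probe = np.array([p != "background" for p in pathway])
    rlo, rhi = config.responder_baseline_range
    q[is_responder_probe] = np.exp(
        rng.uniform(np.log(rlo), np.log(rhi), size=int(is_responder_probe.sum())))
    disp = np.exp(rng.normal(config.dispersion_log_mean,
                             config.dispersion_log_sd, size=n))

    # planted trajectories: per compound, a (n_probes x n_times) log2FC matrix
    truth_rows = []
    fc = {}
    for cpd in config.compounds:
        delta = np.zeros((n, times.size))
        for g_idx in range(n):
            pw = pathway[g_idx]
            spec = None if cpd.inert else cpd.responses.get(pw)
            if spec is None:
                truth_rows.append((cpd.name, probes[g_idx], genes[g_idx], pw,
                                   False, "", "", 0, np.nan))
                continue
            theta, sign = _draw_theta(spec, rng, config.min_amplitude)
            delta[g_idx] = truth_curve(spec.family, theta)(times)
            bmt = true_bmt(spec.family, theta, config.truth_bmr,
                           t_max=10.0 * times[-1])
            truth_rows.append((cpd.name, probes[g_idx], genes[g_idx], pw, True,
                               spec.family, json.dumps(list(theta)), sign,
                               np.nan if bmt is None else bmt))
        fc[cpd.name] = delta

    truth = pd.DataFrame(truth_rows, columns=[
        "compound", "probe", "gene", "pathway", "responder",
        "family", "theta", "direction", "true_bmt"])

    # samples: one shared vehicle arm + one treated arm per compound
    sample_ids, meta_rows, mean_cols = [], [], []
    sigma = np.sqrt(np.log1p(config.library_size_cv ** 2))

    def add_samples(label, conc, vehicle, delta):
        for t in times:
            for r in range(1, reps + 1):
                sid = f"{label}_t{t:g}_r{r}"
                sample_ids.append(sid)
                meta_rows.append((sid, label, conc, t, r, vehicle))
                s = config.library_size_mean * rng.lognormal(-0.5 * sigma ** 2, sigma)
                j = int(np.searchsorted(times, t))
                mean_cols.append(s * q * np.exp2(delta[:, j] if delta is not None else 0.0))

    add_samples(config.vehicle_label, 0.0, True, None)
    for cpd in config.compounds:
        add_samples(cpd.name, cpd.concentration, False, fc[cpd.name])

    mu = np.column_stack(mean_cols)
    # NB draw: gamma-Poisson mixture, per-probe dispersion
    shape_g = 1.0 / np.maximum(disp, 1e-12)
    lam = rng.gamma(shape_g[:, None], 1.0, size=mu.shape) / shape_g[:, None] * mu
    counts = rng.poisson(lam)
    counts = pd.DataFrame(counts.astype(np.int64), index=probes, columns=sample_ids)
    metadata = pd.DataFrame(meta_rows, columns=[
        "sample_id", "compound", "concentration", "time_h", "replicate", "is_vehicle"])
    return counts, metadata, truth


def pathway_gene_sets(truth: pd.DataFrame,
                      include_background: bool = False) -> GeneSetCollection:
    """Gene-symbol sets of the simulated pathways, GMT-ready."""
    sets, desc = {}, {}
    for pw, sub in truth.groupby("pathway"):
        if pw == "background" and not include_background:
            continue
        sets[pw] = frozenset(sub["gene"])
        desc[pw] = "synthetic planted pathway"
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_fixture(counts, metadata, truth, directory,
                  config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write the simulated experiment as plain-text files that round-trip
    through the package's readers: counts.tsv, metadata.tsv, pathways.gmt,
    truth.tsv, and a config.json sidecar echoing the seed and design."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "gmt": directory / "pathways.gmt",
        "truth": directory / "truth.tsv",
        "config": directory / "config.json",
    }
    write_counts(counts, paths["counts"])
    write_metadata(metadata, paths["metadata"])
    write_gmt(pathway_gene_sets(truth), paths["gmt"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if config is not None:
        echo = dataclasses.asdict(config)
        echo["compounds"] = [dataclasses.asdict(c) for c in config.compounds]
        paths["config"].write_text(json.dumps(echo, indent=2, default=str))
    else:
        paths["config"].write_text(json.dumps({"config": None}))
    return paths
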
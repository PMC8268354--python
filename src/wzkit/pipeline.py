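"""End-to-end orchestration: simulate, decompose, classify, test, quantify.

The pipeline wires the stages together on synthetic (or user-supplied) data
and emits a machine-readable JSON report plus human-readable tables, every
output carrying a provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .cnvmodel import classify_individual
from .exprquant import ProbeSet, ReadLibrary, expression_profile
from .sdstats import (AlleleFreqs, association_scan, gof_pearson,
                      hwe_deviation_test, model_expected, MODEL_NAMES)
from .simulate import (Haplotype, MarkerDef, SimConfig, gen_cohort,
                       gen_haplotype_set, gen_reads, gen_trace)
from .tracedecomp import (MixtureEstimate, build_signatures,
                          combine_orientations, decompose)

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp_haplotype(hap: Haplotype) -> Haplotype:
    return Haplotype(hap.id, hap.sequence.translate(_RC)[::-1],
                     hap.chromosome, hap.role, dict(hap.annotations))


def decompose_mixture(haplotypes: Sequence[Haplotype], copy_numbers: Sequence[int],
                      *, noise_cv: float, gain: float, seed: int,
                      window: Optional[tuple[int, int]] = None) -> MixtureEstimate:
    """Simulate forward and reverse traces of a copy mixture and decompose both.

    The default window spans the shortest haplotype so that every copy covers
    it after indel shifting; the reverse orientation re-sequences the same
    window from the other strand.  Returns the orientation-averaged estimate.
    """
    if window is None:
        window = (1, min(len(h.sequence) for h in haplotypes))
    start, end = window
    length = end - start + 1
    estimates = []
    for orient, haps in enumerate((list(haplotypes),
                                   [_revcomp_haplotype(h) for h in haplotypes])):
        trace = gen_trace(haps, copy_numbers, (start, end), noise_cv, gain,
                          seed=seed * 2 + orient)
        sig = build_signatures(haps, start, length)
        estimates.append(decompose(trace, sig))
    return combine_orientations(*estimates)


@dataclass
class PipelineConfig:
    """All knobs for an end-to-end run; YAML/JSON round-trippable."""

    seed: int = 0
    outdir: str = "wzkit_out"
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "decompose": True, "infer_cnv": True,
        "associate": True, "inherit_test": True, "quantify": True})
    n_females: int = 48
    n_males: int = 48
    sex_reversal_rate: float = 0.01
    noise_cv: float = 0.05
    gain: float = 100.0
    base_length: int = 300
    indel_length: int = 3
    n_substitutions: int = 2
    mixtures: list = field(default_factory=lambda: [
        {"label": "female_4copy", "z_copies": 3, "w_copies": 1},
        {"label": "female_3copy", "z_copies": 2, "w_copies": 1},
        {"label": "female_5copy", "z_copies": 4, "w_copies": 1}])
    markers: list = field(default_factory=lambda: [
        {"name": "Banf2_w", "position_kbp": 73178.0, "recomb_fraction": 0.0},
        {"name": "Paics_long", "position_kbp": 73159.0, "recomb_fraction": 0.25},
        {"name": "M1_like", "position_kbp": 73394.0, "recomb_fraction": 0.25}])
    read_length: int = 100
    library_size: int = 2000
    planted_w_reads: int = 5
    planted_z_reads: int = 8
    min_reads: int = 3
    w_threshold: float = 0.10
    max_total: int = 5
    top_factor: float = 1e6

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset parses JSON too
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {"version": __version__, "seed": config.seed,
            "config_hash": config.config_hash()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the report bundle (also written out).

    Stage order: simulate -> decompose -> infer-cnv -> associate ->
    inherit-test -> quantify.  Stage failures propagate with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config), "stages": {}}
    state: dict = {}
    for stage in ("simulate", "decompose", "infer_cnv", "associate",
                  "inherit_test", "quantify"):
        if not config.stages.get(stage, False):
            continue
        try:
            result = _STAGES[stage](config, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = result
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    (outdir / "report.tsv").write_text(make_report(report))
    return report


def _stage_simulate(config: PipelineConfig, state: dict) -> dict:
    state["haplotypes"] = gen_haplotype_set(
        config.base_length, 4, True, config.indel_length,
        config.n_substitutions, seed=config.seed)
    markers = [MarkerDef(**m) for m in config.markers]
    state["markers"] = markers
    sim = SimConfig(seed=config.seed, n_females=config.n_females,
                    n_males=config.n_males,
                    sex_reversal_rate=config.sex_reversal_rate,
                    noise_cv=config.noise_cv, gain=config.gain,
                    read_length=config.read_length,
                    library_size=config.library_size)
    state["cohort"] = gen_cohort(sim, markers)
    w_seq = next(h.sequence for h in state["haplotypes"] if h.role == "banf2w")
    z_seq = state["haplotypes"][0].sequence
    state["probes"] = ProbeSet([("banf2w", w_seq[:32]), ("banf2", z_seq[32:64])])
    state["libraries"] = [
        ReadLibrary("female_gonad", gen_reads(
            [(w_seq, config.planted_w_reads, w_seq[:32]),
             (z_seq, config.planted_z_reads, z_seq[32:64])],
            config.read_length, config.library_size, seed=config.seed + 1)),
        ReadLibrary("male_gonad", gen_reads(
            [(w_seq, 0, w_seq[:32]),
             (z_seq, config.planted_z_reads, z_seq[32:64])],
            config.read_length, config.library_size, seed=config.seed + 2)),
    ]
    return {"n_haplotypes": len(state["haplotypes"]),
            "cohort_size": len(state["cohort"]),
            "n_libraries": len(state["libraries"])}


def _stage_decompose(config: PipelineConfig, state: dict) -> dict:
    haps = state["haplotypes"]
    z_haps = [h for h in haps if h.chromosome == "Z"]
    w_hap = next(h for h in haps if h.role == "banf2w")
    estimates = {}
    for i, mix in enumerate(config.mixtures):
        chosen = z_haps[: 1] if mix["z_copies"] == 1 else z_haps
        copies = _spread_copies(mix["z_copies"], len(chosen)) + [mix["w_copies"]]
        est = decompose_mixture(chosen + [w_hap], copies,
                                noise_cv=config.noise_cv, gain=config.gain,
                                seed=config.seed * 10 + i)
        estimates[mix["label"]] = est
    state["estimates"] = estimates
    return {label: {"proportions": est.proportions, "r2": est.r_squared}
            for label, est in estimates.items()}


def _spread_copies(total: int, n_haps: int) -> list[int]:
    base, extra = divmod(total, n_haps)
    return [base + (1 if i < extra else 0) for i in range(n_haps)]


def _stage_infer_cnv(config: PipelineConfig, state: dict) -> dict:
    out = {}
    for label, est in state["estimates"].items():
        cls = classify_individual(est, "F", threshold=config.w_threshold,
                                  max_total=config.max_total)
        out[label] = {
            "sex_genotype": cls.sex_genotype,
            "w_fraction": cls.w_fraction,
            "ratio": f"{cls.ratio.major}:{cls.ratio.minor}" if cls.ratio else None,
            "total_copies": cls.ratio.total if cls.ratio else 2,
            "concordant": cls.concordant,
        }
    return out


def _stage_associate(config: PipelineConfig, state: dict) -> dict:
    scan = association_scan(state["cohort"], state["markers"],
                            top_factor=config.top_factor)
    state["scan"] = scan
    return {"markers": [{"marker": r.marker, "position_kbp": r.position_kbp,
                         "p": r.p} for r in scan.results],
            "critical_interval_kbp": scan.interval_kbp,
            "span_kbp": scan.span_kbp}


def _stage_inherit_test(config: PipelineConfig, state: dict) -> dict:
    cohort = state["cohort"]
    marker = state["markers"][0].name
    females = cohort[cohort["sex"] == "F"]
    observed = [int((females[marker] == g).sum()) for g in ("ZZ", "WZ", "WW")]
    freqs = AlleleFreqs(0.5, 0.5)
    models = {}
    for name in MODEL_NAMES:
        res = gof_pearson(observed, model_expected(name, freqs, len(females)), name)
        models[name] = {"chi2": res.chi2, "df": res.df, "p": res.p,
                        "expected": list(np.round(res.expected, 3))}
    counts_all = [int((cohort[marker] == g).sum()) for g in ("ZZ", "WZ", "WW")]
    hwe = hwe_deviation_test(counts_all)
    return {"observed_female_counts": observed, "models": models,
            "hwe_deviation": {"counts": counts_all, "chi2": hwe.chi2,
                              "df": hwe.df, "p": hwe.p}}


def _stage_quantify(config: PipelineConfig, state: dict) -> dict:
    profile = expression_profile(state["libraries"], state["probes"],
                                 min_reads=config.min_reads)
    return {"rows": profile.to_dict(orient="records")}


_STAGES = {"simulate": _stage_simulate, "decompose": _stage_decompose,
           "infer_cnv": _stage_infer_cnv, "associate": _stage_associate,
           "inherit_test": _stage_inherit_test, "quantify": _stage_quantify}


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.2g}"
    return str(x)


def make_report(report: dict) -> str:
    """Human-readable tables in pipeline order, 2 significant figures.

    Full precision lives in the JSON report; this is the compact view.
    """
    prov = report.get("provenance", {})
    lines = [f"# wzkit {prov.get('version', '?')} seed={prov.get('seed', '?')} "
             f"config={prov.get('config_hash', '?')}"]
    stages = report.get("stages", {})
    if "associate" in stages:
        lines += ["", "## association", "marker\tposition_kbp\tp"]
        for row in stages["associate"]["markers"]:
            lines.append(f"{row['marker']}\t{_fmt(row['position_kbp'])}\t{_fmt(row['p'])}")
        span = stages["associate"].get("span_kbp")
        if span is not None:
            lines.append(f"critical_span_kbp\t{_fmt(span)}")
    if "inherit_test" in stages:
        lines += ["", "## inheritance models", "model\tchi2\tdf\tp"]
        for name, res in stages["inherit_test"]["models"].items():
            lines.append(f"{name}\t{_fmt(res['chi2'])}\t{res['df']}\t{_fmt(res['p'])}")
    if "infer_cnv" in stages:
        lines += ["", "## copy models", "mixture\tratio\tw_fraction\tconcordant"]
        for label, res in stages["infer_cnv"].items():
            lines.append(f"{label}\t{res['ratio']}\t{_fmt(res['w_fraction'])}\t"
                         f"{res['concordant']}")
    if "quantify" in stages:
        lines += ["", "## expression", "library\tprobe\thits\tfpkm\tdetected"]
        for row in stages["quantify"]["rows"]:
            lines.append(f"{row['library']}\t{row['probe']}\t{row['hits']}\t"
                         f"{_fmt(row['fpkm'])}\t{row['detected']}")
    return "\n".join(lines) + "\n"
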
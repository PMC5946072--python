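"""End-to-end pipeline orchestration.

Runs simulate -> call -> overlap -> tally -> metagene -> cdf -> decay ->
mirna -> summary from one config, writing each stage's outputs under
``<outdir>/<stage>/`` and a run manifest with the config echo and a sha256
per output file. Completed stages are skipped on rerun (resume) as long as
their outputs still exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import expression as expr_mod
from . import metagene as metagene_mod
from . import mirna as mirna_mod
from . import sites as sites_mod
from .annotation import (
    CohortDesign,
    ExpressionTable,
    GenomicInterval,
    read_transcript_models,
)
from .decay import compare_half_lives, fit_series, read_decay_tsv
from .simulate import SimulationConfig, count_fragments_in_windows, simulate_all
from .sites import M6ASite

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "overlap", "tally", "metagene", "cdf",
          "decay", "mirna", "summary")


@dataclass
class RunConfig:
    """Full-run configuration; unknown keys are rejected on load."""

    outdir: str = "m6a_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: dict = field(default_factory=dict)
    window: int = 50
    step: int = 25
    q_threshold: float = 0.05
    pseudocount: float = 0.5
    epsilon: float = 0.01
    bins: tuple[int, int, int] = (20, 50, 30)
    anchor_window: int = 300
    decay_method: str = "loglinear"
    mirna_p: float = 0.05
    mirna_z_ratio: float = 1.5
    mirna_fdr: float = 0.3
    mirna_top: int = 20
    mirna_floor: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(self.simulation) - known_sim
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "bins" in raw:
            raw["bins"] = tuple(raw["bins"])
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        if "fragment_length" in kwargs:
            kwargs["fragment_length"] = tuple(kwargs["fragment_length"])
        if "decay_timepoints" in kwargs:
            kwargs["decay_timepoints"] = tuple(kwargs["decay_timepoints"])
        return SimulationConfig(**kwargs)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["bins"] = list(d["bins"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_fragments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return df


def read_sites_bed(path) -> list[M6ASite]:
    """Read sites written by :func:`m6aging.sites.write_sites_bed`."""
    cols = ["chrom", "start", "end", "motif_class", "score", "strand",
            "transcript_id", "enrichment", "qvalue", "ip_fpkm", "fragment_count"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return [
        M6ASite(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
            transcript_id=str(r.transcript_id),
            motif_class=str(r.motif_class),
            ip_fpkm=float(r.ip_fpkm),
            enrichment=float(r.enrichment),
            qvalue=float(r.qvalue),
            fragment_count=int(r.fragment_count),
        )
        for r in df.itertuples()
    ]


def _read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


class Pipeline:
    """Stateful runner; see :func:`run_pipeline` for the one-shot interface."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()
        self.state: dict = {}

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                m = json.load(fh)
            if m.get("config") == self.cfg.to_jsonable():
                return m
            logger.info("config changed; previous manifest ignored")
        return {"config": self.cfg.to_jsonable(), "stages": {}}

    def _save_manifest(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)

    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def _complete(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "status": "complete",
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        }
        self._save_manifest()

    def _is_complete(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry.get("status") != "complete":
            return False
        return all((self.outdir / rel).exists() for rel in entry["outputs"])

    # --- lazy loaders (support resume: reload prior-stage outputs from disk)

    def models(self):
        if "models" not in self.state:
            self.state["models"] = read_transcript_models(
                self._stage_dir("simulate") / "transcripts.bed12", "bed12"
            )
        return self.state["models"]

    def sequences(self):
        if "sequences" not in self.state:
            self.state["sequences"] = _read_fasta(
                self._stage_dir("simulate") / "transcripts.fa"
            )
        return self.state["sequences"]

    def registry(self):
        if "registry" not in self.state:
            with open(self._stage_dir("simulate") / "truth.json") as fh:
                self.state["registry"] = json.load(fh)
        return self.state["registry"]

    def sites(self, cohort: str) -> list[M6ASite]:
        key = f"sites_{cohort}"
        if key not in self.state:
            self.state[key] = read_sites_bed(
                self._stage_dir("call") / f"sites_{cohort}.bed"
            )
        return self.state[key]

    # --- stages

    def stage_simulate(self) -> list[Path]:
        d = self._stage_dir("simulate")
        registry = simulate_all(self.cfg.sim_config(), d)
        self.state["registry"] = registry
        return sorted(d.iterdir())

    def stage_call(self) -> list[Path]:
        d = self._stage_dir("call")
        sim = self._stage_dir("simulate")
        models = self.models()
        seqs = self.sequences()
        out = []
        for cohort in ("young", "old"):
            ip = read_fragments_bed(sim / f"fragments_{cohort}_ip.bed")
            inp = read_fragments_bed(sim / f"fragments_{cohort}_input.bed")
            windows = count_fragments_in_windows(
                ip, inp, models, self.cfg.window, self.cfg.step
            )
            called = sites_mod.call_m6a_sites(
                windows, len(ip), len(inp),
                q_threshold=self.cfg.q_threshold, pseudocount=self.cfg.pseudocount,
            )
            called = sites_mod.assign_motifs(called, seqs)
            self.state[f"sites_{cohort}"] = called
            path = d / f"sites_{cohort}.bed"
            sites_mod.write_sites_bed(called, path)
            out.append(path)
            logger.info("called %d sites in %s cohort", len(called), cohort)
        return out

    def stage_overlap(self) -> list[Path]:
        d = self._stage_dir("overlap")
        res = sites_mod.overlap_sites(self.sites("young"), self.sites("old"))
        path = d / "overlap.json"
        with open(path, "w") as fh:
            json.dump(res.counts(), fh, indent=1, sort_keys=True)
        return [path]

    def stage_tally(self) -> list[Path]:
        d = self._stage_dir("tally")
        models = {m.transcript_id: m for m in self.models()}
        out = []
        for cohort in ("young", "old"):
            s = self.sites(cohort)
            bt = sites_mod.tally_by_biotype(s, models)
            p1 = d / f"biotype_{cohort}.tsv"
            pd.Series(bt, name="count").rename_axis("biotype").to_csv(p1, sep="\t")
            p2 = d / f"motif_{cohort}.tsv"
            sites_mod.tally_by_motif(s).to_csv(p2, sep="\t", index=False)
            out += [p1, p2]
        return out

    def stage_metagene(self) -> list[Path]:
        d = self._stage_dir("metagene")
        models = {m.transcript_id: m for m in self.models()}
        out = []
        for cohort in ("young", "old"):
            prof = metagene_mod.metagene_profile(
                self.sites(cohort), models,
                bins=self.cfg.bins, anchor_window=self.cfg.anchor_window,
            )
            path = d / f"profile_{cohort}.tsv"
            prof.to_frame().to_csv(path, sep="\t", index=False)
            out.append(path)
            self.state[f"profile_{cohort}"] = prof
        return out

    def stage_cdf(self) -> list[Path]:
        d = self._stage_dir("cdf")
        sim = self._stage_dir("simulate")
        expr = ExpressionTable.read_tsv(sim / "expression_fpkm.tsv")
        design = CohortDesign.read_tsv(sim / "design.tsv")
        methylated = {s.transcript_id for c in ("young", "old") for s in self.sites(c)}
        records = expr_mod.log2_fold_changes(
            expr, design, epsilon=self.cfg.epsilon, methylated=methylated
        )
        report = expr_mod.stratified_cdf_report(
            records,
            {"methylated": lambda r: r.methylated,
             "rest": lambda r: not r.methylated},
        )
        p1 = d / "ks.tsv"
        report.to_frame().to_csv(p1, sep="\t", index=False)
        rows = []
        for name, (x, f) in report.ecdfs.items():
            rows.append(pd.DataFrame({"stratum": name, "x": x, "F": f}))
        p2 = d / "ecdf.tsv"
        pd.concat(rows).to_csv(p2, sep="\t", index=False)
        # methylation level vs steady-state abundance
        m6a_fpkm: dict[str, float] = {}
        for s in self.sites("young"):
            m6a_fpkm[s.transcript_id] = max(m6a_fpkm.get(s.transcript_id, 0.0), s.ip_fpkm)
        total = expr.values.mean(axis=1).to_dict()
        p3 = d / "scatter.tsv"
        if len(set(m6a_fpkm) & set(total)) >= 3:
            table, rho, p = expr_mod.methylation_expression_scatter(m6a_fpkm, total)
            table.to_csv(p3, sep="\t", index=False)
            self.state["scatter_rho"], self.state["scatter_p"] = rho, p
        self.state["cdf_report"] = report
        return [p1, p2] + ([p3] if p3.exists() else [])

    def stage_decay(self) -> list[Path]:
        d = self._stage_dir("decay")
        series = read_decay_tsv(self._stage_dir("simulate") / "decay_ct.tsv")
        fits = [(s.condition, s.replicate, fit_series(s, self.cfg.decay_method))
                for s in series]
        summary, comparisons = compare_half_lives(fits)
        p1, p2, p3 = d / "fits.tsv", d / "summary.tsv", d / "comparisons.tsv"
        pd.DataFrame(
            [{"condition": c, "replicate": r, "t_half": f.t_half, "k": f.k,
              "r_squared": f.r_squared, "flag": f.flag} for c, r, f in fits]
        ).to_csv(p1, sep="\t", index=False)
        summary.to_csv(p2, sep="\t", index=False)
        comparisons.to_csv(p3, sep="\t", index=False)
        self.state["decay_summary"] = summary
        self.state["decay_comparisons"] = comparisons
        return [p1, p2, p3]

    def stage_mirna(self) -> list[Path]:
        d = self._stage_dir("mirna")
        m = mirna_mod.MirnaMatrix.read_tsv(
            self._stage_dir("simulate") / "mirna_intensity.tsv"
        )
        design = CohortDesign.read_tsv(self._stage_dir("simulate") / "design.tsv")
        m.detectable = mirna_mod.detect_mirnas(m, design, floor=self.cfg.mirna_floor)
        z = mirna_mod.zscore_normalize(m)
        records = mirna_mod.z_ratio(
            z, design, p_threshold=self.cfg.mirna_p,
            z_ratio_threshold=self.cfg.mirna_z_ratio,
            fdr_threshold=self.cfg.mirna_fdr,
        )
        p1 = d / "zratio.tsv"
        mirna_mod.records_frame(records).to_csv(p1, sep="\t", index=False)
        up, down = mirna_mod.top_table(records, k=self.cfg.mirna_top)
        p2, p3 = d / "top_up.tsv", d / "top_down.tsv"
        up.to_csv(p2, sep="\t", index=False)
        down.to_csv(p3, sep="\t", index=False)
        self.state["mirna_records"] = records
        return [p1, p2, p3]

    def stage_summary(self) -> list[Path]:
        # summary is assembled from stage output files so that resumed runs
        # (where earlier stages were skipped) still summarize correctly
        d = self._stage_dir("summary")
        summary: dict = {"seed": self.cfg.seed}
        if self.cfg.stages.get("call"):
            ny, no = len(self.sites("young")), len(self.sites("old"))
            summary["n_sites_young"] = ny
            summary["n_sites_old"] = no
            summary["fewer_sites_in_old"] = no < ny
        if self.cfg.stages.get("overlap"):
            with open(self._stage_dir("overlap") / "overlap.json") as fh:
                summary["overlap"] = json.load(fh)
        if self.cfg.stages.get("cdf"):
            ks = pd.read_csv(self._stage_dir("cdf") / "ks.tsv", sep="\t")
            row = ks[(ks["stratum_a"] == "methylated") & (ks["stratum_b"] == "rest")]
            if len(row):
                summary["ks_methylated_vs_rest"] = {
                    "D": float(row["D"].iloc[0]), "p": float(row["p"].iloc[0])
                }
        if self.cfg.stages.get("decay"):
            ds = pd.read_csv(self._stage_dir("decay") / "summary.tsv", sep="\t")
            summary["t_half_by_condition"] = dict(
                zip(ds["condition"], ds["mean_t_half"])
            )
        if self.cfg.stages.get("mirna"):
            zr = pd.read_csv(self._stage_dir("mirna") / "zratio.tsv", sep="\t")
            summary["mirna_calls"] = zr["call"].value_counts().to_dict()
        path = d / "summary.json"
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        self.state["summary"] = summary
        return [path]

    def run(self) -> dict:
        for stage in STAGES:
            if not self.cfg.stages.get(stage, True):
                logger.info("stage %s disabled", stage)
                continue
            if self._is_complete(stage):
                logger.info("stage %s already complete; skipping", stage)
                continue
            logger.info("running stage %s", stage)
            try:
                outputs = getattr(self, f"stage_{stage}")()
            except Exception:
                self.manifest["stages"][stage] = {"status": "failed"}
                self._save_manifest()
                raise
            self._complete(stage, outputs)
        return self.manifest


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns the manifest."""
    return Pipeline(cfg).run()
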
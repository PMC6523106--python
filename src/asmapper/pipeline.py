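"""End-to-end orchestration: classify -> structure-filter -> loci ->
analytics / expression / ribo / conservation, driven by a YAML config.

Each stage writes plain-text outputs under ``outdir`` and records its
headline counters in a manifest (JSON) together with input checksums and
the config snapshot, so a run is auditable and reruns with unchanged
inputs are byte-identical. When a manifest from a previous run exists and
the input checksums match, the TSS and locus stages are resumed from
their on-disk outputs instead of recomputed; the cheap downstream stages
are always recomputed from those.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import analytics, conservation, expression, io as aio, structure, tss as tss_mod
from .io import loci_to_frame
from .loci import build_loci
from .model import (ANTISENSE, DOWNSTREAM_ANTISENSE, AsRnaLocus, Gene,
                    PipelineConfig, ProfileTrack, Tss)

logger = logging.getLogger(__name__)

STAGES = ("tss", "classify", "mfe_filter", "loci", "analytics", "counts",
          "ribo", "conserve")


class PipelineConfigError(ValueError):
    """Malformed or incomplete configuration (CLI exit code 2)."""


class PipelineInputError(ValueError):
    """Missing or unreadable input file (CLI exit code 3)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config_path: str | Path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise PipelineConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PipelineConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a YAML mapping")
    for key in ("genome", "annotation", "outdir"):
        if key not in cfg:
            raise PipelineConfigError(f"config missing required key: {key!r}")
    if "tss" not in cfg and not ("tex_plus" in cfg and "tex_minus" in cfg):
        raise PipelineConfigError(
            "config needs either 'tss' (BED6) or 'tex_plus'/'tex_minus' tracks")
    if "libraries" not in cfg or not cfg["libraries"]:
        raise PipelineConfigError("config needs a non-empty 'libraries' list")
    return cfg


class Pipeline:
    """Stateful runner; stages fill attributes in dependency order."""

    def __init__(self, config_path: str | Path):
        self.config_path = Path(config_path)
        self.raw = load_config(config_path)
        self.base = self.config_path.parent
        self.params = PipelineConfig(**self.raw.get("params", {}))
        self.outdir = self._resolve(self.raw["outdir"], must_exist=False)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.counters: dict[str, int | float] = {}
        self.outputs: dict[str, str] = {}
        self.input_checksums: dict[str, str] = {}
        self._collect_inputs()
        self.genome = aio.read_genome(self._input("genome"))
        self.genes = aio.read_annotation(self._input("annotation"))
        self.lengths = {name: len(seq) for name, seq in self.genome.items()}
        self.sites: list[Tss] | None = None
        self.retained: list[Tss] | None = None
        self.removed: list[Tss] | None = None
        self.loci: list[AsRnaLocus] | None = None
        self._previous_manifest = self._load_previous_manifest()

    # -- plumbing ----------------------------------------------------------

    def _resolve(self, p: str, must_exist: bool = True) -> Path:
        path = Path(p)
        if not path.is_absolute():
            path = self.base / path
        if must_exist and not path.exists():
            raise PipelineInputError(f"input file not found: {path}")
        return path

    def _collect_inputs(self) -> None:
        """Resolve and checksum every referenced input before any
        computation, so missing files fail fast."""
        self._paths: dict[str, Path] = {}

        def add(name: str, value) -> None:
            if isinstance(value, str):
                self._paths[name] = self._resolve(value)
            elif isinstance(value, Mapping):
                for sub, v in value.items():
                    add(f"{name}.{sub}", v)

        for key in ("genome", "annotation", "tss", "tex_plus", "tex_minus"):
            if key in self.raw:
                add(key, self.raw[key])
        for lib in self.raw["libraries"]:
            if "id" not in lib:
                raise PipelineConfigError("each library needs an 'id'")
            for key in ("coverage", "three_prime", "fragments"):
                if key in lib:
                    add(f"lib.{lib['id']}.{key}", lib[key])
        for section in ("ribo", "conservation"):
            if section in self.raw:
                add(section, self.raw[section])
        for name, path in self._paths.items():
            self.input_checksums[name] = _sha256(path)

    def _input(self, name: str) -> Path:
        if name not in self._paths:
            raise PipelineInputError(f"config does not define input {name!r}")
        return self._paths[name]

    def _has_input(self, name: str) -> bool:
        return name in self._paths

    def _out(self, rel: str) -> Path:
        path = self.outdir / rel
        self.outputs[rel] = str(path)
        return path

    def _load_previous_manifest(self) -> dict | None:
        path = self.outdir / "manifest.json"
        if not path.exists():
            return None
        try:
            with open(path) as fh:
                return json.load(fh)
        except (OSError, json.JSONDecodeError):
            return None

    def _resumable(self, *output_rels: str) -> bool:
        prev = self._previous_manifest
        if prev is None:
            return False
        if prev.get("input_checksums") != self.input_checksums:
            return False
        if prev.get("config") != self.raw:
            return False
        return all((self.outdir / rel).exists() for rel in output_rels)

    def _read_stranded_pair(self, name: str, library_id: str,
                            kind: str) -> list[ProfileTrack]:
        tracks = []
        for sub, strand in (("fwd", "+"), ("rev", "-")):
            tracks.append(aio.read_profile(
                self._input(f"{name}.{sub}"), self.lengths, strand=strand,
                library_id=library_id, kind=kind))
        return tracks

    # -- stages ------------------------------------------------------------

    def stage_tss(self) -> None:
        if self._has_input("tss"):
            self.sites = aio.read_tss_bed(self._input("tss"))
        else:
            sites: list[Tss] = []
            plus = self._read_stranded_pair("tex_plus", "tex_plus", "five_prime")
            minus = self._read_stranded_pair("tex_minus", "tex_minus", "five_prime")
            for p, m in zip(plus, minus):
                sites.extend(tss_mod.call_tss(p, m, self.params.tss_caller))
            self.sites = sites
        self.counters["n_tss"] = len(self.sites)

    def stage_classify(self) -> None:
        if self.sites is None:
            self.stage_tss()
        rel = "tss_classified.bed"
        if self._resumable(rel):
            self.sites = aio.read_tss_bed(self.outdir / rel)
            self._out(rel)
            logger.info("classify: resumed from %s", rel)
        else:
            tss_mod.classify_all(self.sites, self.genes, self.params.da_window_nt)
            tss_mod.number_sites(self.sites)
            aio.write_tss_bed(self.sites, self._out(rel))
        self.counters["n_atss"] = sum(
            1 for t in self.sites if t.tss_class == ANTISENSE)
        self.counters["n_datss"] = sum(
            1 for t in self.sites if t.tss_class == DOWNSTREAM_ANTISENSE)

    def stage_mfe_filter(self) -> None:
        if self.sites is None or "n_atss" not in self.counters:
            self.stage_classify()
        windows = structure.tile_genome_mfe(
            self.genome, self.params.mfe_window_nt, self.params.mfe_offset_nt,
            self.params.folder)
        cutoff = structure.mfe_cutoff([w.mfe for w in windows],
                                      self.params.mfe_quantile)
        atss = [t for t in self.sites if t.tss_class == ANTISENSE]
        others = [t for t in self.sites if t.tss_class != ANTISENSE]
        retained_a, removed = structure.filter_structured_atss(
            atss, self.genome, cutoff, self.params.mfe_window_nt,
            self.params.folder)
        self.retained = retained_a + [t for t in others
                                      if t.tss_class == DOWNSTREAM_ANTISENSE]
        self.removed = removed
        import pandas as pd

        pd.DataFrame([{"replicon": w.replicon, "start": w.start,
                       "strand": w.strand, "mfe": w.mfe} for w in windows]
                     ).to_csv(self._out("mfe_windows.tsv"), sep="\t", index=False)
        aio.write_tss_bed(self.retained, self._out("tss_retained.bed"))
        aio.write_tss_bed(removed, self._out("tss_removed_mfe.bed"))
        self.counters["mfe_cutoff"] = cutoff
        self.counters["n_removed_mfe"] = len(removed)
        self.counters["n_atss_retained"] = len(retained_a)

    def _library_tracks(self, kind: str) -> list[ProfileTrack]:
        tracks = []
        for lib in self.raw["libraries"]:
            tracks.extend(self._read_stranded_pair(
                f"lib.{lib['id']}.{kind}", lib["id"], kind))
        return tracks

    def stage_loci(self) -> None:
        if self.retained is None:
            self.stage_mfe_filter()
        rel = "loci.gff3"
        if self._resumable(rel):
            self.loci = aio.read_loci_gff3(self.outdir / rel)
            self._out(rel)
            logger.info("loci: resumed from %s", rel)
        else:
            three_prime = self._library_tracks("three_prime")
            coverage = self._library_tracks("coverage")
            self.loci = build_loci(self.retained, three_prime, coverage,
                                   self.params, genes=self.genes)
            aio.write_loci_gff3(self.loci, self._out(rel))
        loci_to_frame(self.loci).to_csv(self._out("loci.tsv"), sep="\t",
                                        index=False)
        self.counters["n_loci"] = len(self.loci)
        self.counters["n_loci_two_genes"] = sum(
            1 for l in self.loci if len(l.cognate_genes) > 1)

    def stage_analytics(self) -> None:
        if self.loci is None:
            self.stage_loci()
        import pandas as pd

        genes_by_tag = {g.locus_tag: g for g in self.genes}
        atss = [t for t in self.retained if t.tss_class == ANTISENSE]
        hist = analytics.position_histogram(atss, genes_by_tag,
                                            self.params.n_partitions)
        pd.DataFrame({"partition": np.arange(len(hist)), "count": hist}
                     ).to_csv(self._out("atss_position_histogram.tsv"),
                              sep="\t", index=False)
        lo, hi = self.params.promoter_window
        if atss:
            fm = analytics.frequency_matrix(
                [(t.replicon, t.position, t.strand) for t in atss],
                self.genome, list(range(lo, hi + 1)))
            analytics.frequency_matrix_frame(fm).to_csv(
                self._out("promoter_frequency_matrix.tsv"), sep="\t", index=False)
        lo3, hi3 = self.params.three_prime_window
        ends = [(l.replicon, l.end - 1 if l.strand == "+" else l.start, l.strand)
                for l in self.loci
                if l.end_support >= self.params.min_end_support]
        if ends:
            fm3 = analytics.frequency_matrix(ends, self.genome,
                                             list(range(lo3, hi3 + 1)))
            analytics.frequency_matrix_frame(fm3).to_csv(
                self._out("three_prime_frequency_matrix.tsv"), sep="\t",
                index=False)
        rows = []
        for locus in self.loci:
            for tag in locus.cognate_genes:
                gene = genes_by_tag.get(tag)
                if gene and analytics.five_prime_overlap(
                        locus, gene, self.params.five_prime_extension_nt):
                    rows.append({"asrna_id": locus.asrna_id, "gene": tag})
        pd.DataFrame(rows, columns=["asrna_id", "gene"]).to_csv(
            self._out("five_prime_overlap_candidates.tsv"), sep="\t", index=False)
        self.counters["n_five_prime_overlap"] = len({r["asrna_id"] for r in rows})

    def stage_counts(self) -> None:
        if self.loci is None:
            self.stage_loci()
        libs_with_fragments = [lib for lib in self.raw["libraries"]
                               if "fragments" in lib]
        if not libs_with_fragments:
            logger.info("counts: no fragment files configured; stage skipped")
            return
        features = {g.locus_tag: (g.replicon, g.start, g.end, g.strand)
                    for g in self.genes}
        features.update({l.asrna_id: (l.replicon, l.start, l.end, l.strand)
                         for l in self.loci})
        fragments = {
            lib["id"]: aio.read_fragments_bed(
                self._input(f"lib.{lib['id']}.fragments"))
            for lib in libs_with_fragments}
        matrix = expression.count_fragments(features, fragments)
        matrix.to_csv(self._out("count_matrix.tsv"), sep="\t",
                      index_label="feature")
        table = expression.expression_table(matrix, self.loci)
        table.to_csv(self._out("expression_flags.tsv"), sep="\t", index=False)
        self.counters["n_expression_candidates"] = (
            int(table["candidate"].sum()) if len(table) else 0)

    def stage_ribo(self) -> None:
        if self.loci is None:
            self.stage_loci()
        if not self._has_input("ribo.coverage.fwd"):
            logger.info("ribo: no Ribo-seq tracks configured; stage skipped")
            return
        import pandas as pd

        cov = self._read_stranded_pair("ribo.coverage", "ribo", "ribo")
        starts = self._read_stranded_pair("ribo.starts", "ribo", "five_prime")
        rows = []
        for locus in self.loci:
            c = [t for t in cov if t.strand == locus.strand
                 and t.replicon == locus.replicon]
            s = [t for t in starts if t.strand == locus.strand
                 and t.replicon == locus.replicon]
            frac, reads, flag = expression.rancrna_filter(locus, c, s, self.params)
            rows.append({"asrna_id": locus.asrna_id,
                         "coverage_fraction": frac, "reads": reads,
                         "is_rancrna": flag})
        df = pd.DataFrame(rows)
        df.to_csv(self._out("rancrna.tsv"), sep="\t", index=False)
        self.counters["n_rancrna"] = int(df["is_rancrna"].sum()) if len(df) else 0

    def stage_conserve(self) -> None:
        if self.loci is None:
            self.stage_loci()
        if not self._has_input("conservation.orthologs"):
            logger.info("conserve: no ortholog inputs configured; stage skipped")
            return
        pairs_tsv = aio.read_ortholog_table(self._input("conservation.orthologs"))
        genes_b = aio.read_annotation(self._input("conservation.annotation_b"))
        sites_b = aio.read_tss_bed(self._input("conservation.tss_b"))
        # classify species-B sites against species-B annotation
        tss_mod.classify_all(sites_b, genes_b, self.params.da_window_nt)
        atss_b = [t for t in sites_b if t.tss_class == ANTISENSE]
        records, pairs = conservation.conservation_scan(
            pairs_tsv, self.loci, atss_b,
            {g.locus_tag: g for g in self.genes},
            {g.locus_tag: g for g in genes_b},
            self.params.n_partitions)
        records.to_csv(self._out("conservation_records.tsv"), sep="\t",
                       index=False)
        pairs.to_csv(self._out("conservation_pairs.tsv"), sep="\t", index=False)
        conservation.d_histogram(records).to_csv(
            self._out("conservation_D_histogram.tsv"), sep="\t", index=False)
        summary = conservation.conservation_summary(records, pairs)
        self.counters.update({f"conservation_{k}": v for k, v in summary.items()})

    # -- driver ------------------------------------------------------------

    def run(self, stages: Sequence[str] | None = None) -> dict:
        requested = list(stages) if stages is not None else list(STAGES)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")
        for stage in STAGES:
            if stage in requested:
                getattr(self, f"stage_{stage}")()
        manifest = {
            "config": self.raw,
            "config_path": str(self.config_path),
            "input_checksums": self.input_checksums,
            "outputs": self.outputs,
            "counters": self.counters,
            "stages_run": [s for s in STAGES if s in requested],
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline counters: %s", self.counters)
        return manifest


def run_pipeline(config_path: str | Path,
                 stages: Sequence[str] | None = None) -> dict:
    """Run the pipeline (or a subset of stages) from a YAML config; returns
    the output manifest."""
    return Pipeline(config_path).run(stages)
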
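"""End-to-end orchestration: from call tables and annotations to pathway
calls, DMRs, meta-plots, structure/enrichment tables, cleavage and competence
reports, with a run record for reproducibility auditing.

The run configuration is a YAML file::

    silent_manifest: silent.cfg.yaml     # required
    active_manifest: active.cfg.yaml     # optional: active stages skipped if absent
    te_gff: tes.gff3                     # required
    gene_gff: genes.gff3                 # optional
    srna_counts: srna_counts.tsv         # optional sRNA/cleavage inputs
    srna_totals: srna_totals.tsv
    pare: pare.tsv
    rnaseq: rnaseq.tsv
    domain_hits: domain_hits.tsv         # optional structure inputs
    coverage_intervals: coverage_intervals.tsv
    landmarks: landmarks.tsv
    dmr_pairs: [[wt, polV]]              # genotype pairs for DMR calling
    seed: 0

Relative paths resolve against the config file's directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import classifier, metaplot, methylome, srna, te_structure

log = logging.getLogger("methylpath")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful runner; use :func:`run_all` for the one-shot entry point."""

    def __init__(self, config_path, out_dir):
        self.config_path = Path(config_path)
        base = self.config_path.parent
        with open(self.config_path) as fh:
            self.run_cfg = yaml.safe_load(fh) or {}
        self.paths = {k: (base / v if not Path(v).is_absolute() else Path(v))
                      for k, v in self.run_cfg.items()
                      if isinstance(v, str) and k.endswith(
                          ("manifest", "gff", "counts", "totals", "pare",
                           "rnaseq", "hits", "intervals", "landmarks"))}
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.run_cfg.get("seed", 0))
        self.timings: dict[str, float] = {}
        self.outputs: list[Path] = []
        self.warnings: list[str] = []

    # -- helpers ----------------------------------------------------------

    def _stage(self, name):
        runner = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                runner.timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done (%.2fs)", name, runner.timings[name])

        return _Timer()

    def _write(self, df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = self.out / name
        df.to_csv(path, sep="\t", na_rep="NA", index=index)
        self.outputs.append(path)
        return path

    # -- stages -----------------------------------------------------------

    def run(self) -> Path:
        with self._stage("load"):
            self.tes = mio.read_features(self.paths["te_gff"], kind="TE")
            manifests = {}
            manifests["silent"] = mio.read_manifest(self.paths["silent_manifest"])
            if "active_manifest" in self.paths:
                manifests["active"] = mio.read_manifest(self.paths["active_manifest"])
            else:
                self.warnings.append("no active manifest: active stages skipped")
                warnings.warn("no active manifest: active stages skipped")
            self.manifests = manifests
            self.config = manifests["silent"][1]
            self.tables = {
                bg: {role: mio.read_cytosine_table(path)
                     for role, path in man.paths.items()}
                for bg, (man, _cfg) in manifests.items()}

        self.calls: dict[str, pd.DataFrame] = {}
        self.counts: dict[str, pd.Series] = {}
        for bg in self.manifests:
            with self._stage(f"classify_{bg}"):
                man, cfg = self.manifests[bg]
                matrix = methylome.build_matrix(
                    {mio.canonical_role(r, bg): t
                     for r, t in self.tables[bg].items()
                     if r in mio.required_roles(bg)},
                    self.tes, "CHH", cfg)
                calls, counts = classifier.categorize_genome(matrix, bg, cfg)
                self.calls[bg], self.counts[bg] = calls, counts
                self._write(calls, f"rddm_calls_{bg}.tsv")
                self._write(counts.to_frame(), f"category_counts_{bg}.tsv")
                self._write(matrix.levels, f"chh_matrix_{bg}.tsv")

        if len(self.calls) == 2:
            with self._stage("category_shift"):
                shift = classifier.category_shift(self.calls["silent"],
                                                  self.calls["active"])
                self._write(shift, "category_shift.tsv")

        with self._stage("dmr"):
            pairs = self.run_cfg.get("dmr_pairs") or [
                [self.manifests["silent"][0].ref_role, "polV"]]
            for role_a, role_b in pairs:
                bg = "silent" if role_a in self.tables.get("silent", {}) else "active"
                dms = methylome.call_dms(self.tables[bg][role_a],
                                         self.tables[bg][role_b],
                                         alpha=self.config.dms_alpha,
                                         context="CHH")
                regions = methylome.merge_dms(dms,
                                              max_gap=self.config.dmr_max_gap,
                                              min_dms=self.config.dmr_min_dms)
                path = self.out / f"dmrs_{role_a}_vs_{role_b}.bed"
                methylome.write_dmrs_bed(regions, path)
                self.outputs.append(path)
                log.info("DMRs %s vs %s: %d DMSs -> %d regions",
                         role_a, role_b, len(dms), len(regions))

        with self._stage("metaplot"):
            ref_role = self.manifests["silent"][0].ref_role
            calls_ref = self.tables["silent"][ref_role]
            for anchor in ("five_prime", "three_prime"):
                prof = metaplot.profile_features(
                    self.tes, calls_ref, bin=self.config.metaplot_bin,
                    flank=self.config.metaplot_flank, anchor=anchor,
                    context="CHH", body_cap=self.config.metaplot_body_cap)
                path = self.out / f"metaplot_te_{anchor}.tsv"
                prof.to_tsv(path)
                self.outputs.append(path)

        with self._stage("structure"):
            bg = "active" if "active" in self.calls else "silent"
            covered = self.calls[bg][self.calls[bg]["category"] != "UNCOVERED"]
            te_lengths = {f.id: f.length for f in self.tes}
            sizes, chi2, contrasts = te_structure.size_category_table(
                covered, te_lengths)
            self._write(sizes, "size_by_category.tsv")
            if chi2 is not None:
                self._write(pd.DataFrame(
                    [{"statistic": chi2.statistic, "df": chi2.df,
                      "p_value": chi2.p_value,
                      "n_significant_contrasts": len(contrasts)}]),
                    "size_homogeneity.tsv", index=False)
            if "domain_hits" in self.paths:
                hits = pd.read_csv(self.paths["domain_hits"], sep="\t")
                profiles = te_structure.profiles_from_hits(hits, self.config)
                enrich = te_structure.domain_enrichment(profiles, covered)
                self._write(enrich, "domain_enrichment.tsv")

        if "pare" in self.paths:
            with self._stage("cleavage"):
                records = srna.read_pare_table(self.paths["pare"])
                te_ids = [f.id for f in self.tes]
                self.dependency = {}
                for bg in ("silent", "active"):
                    if any(r.background == bg for r in records):
                        dep = srna.dependency_table(records, bg, te_ids,
                                                    self.config)
                        self.dependency[bg] = dep
                        self._write(dep, f"cleavage_dependency_{bg}.tsv")
                if len(self.dependency) == 2:
                    kept = srna.filter_sites(records, self.config.cleavage_alpha)
                    rows = []
                    for fid in te_ids:
                        silent = {r.site for r in kept
                                  if r.feature_id == fid and r.background == "silent"}
                        active = {r.site for r in kept
                                  if r.feature_id == fid and r.background == "active"}
                        label, (n_s, n_a) = srna.site_retention(silent, active)
                        rows.append((fid, label, n_s, n_a))
                    retention = pd.DataFrame(
                        rows, columns=["feature_id", "retention", "n_silent",
                                       "n_active"]).set_index("feature_id")
                    self._write(retention, "site_retention.tsv")

        if "srna_counts" in self.paths:
            with self._stage("srna"):
                counts = srna.read_srna_counts(self.paths["srna_counts"])
                totals = pd.read_csv(self.paths["srna_totals"], sep="\t")
                totals = dict(zip(totals["library_id"], totals["total_18_28"]))
                region_lengths = {f.id: f.length for f in self.tes}
                counts = counts[counts["feature_id"].isin(region_lengths)]
                profiles = srna.profiles_from_table(counts, totals, region_lengths)
                if getattr(self, "dependency", None) and "active" in self.dependency:
                    dep_map = self.dependency["active"]["dependency"].to_dict()
                    table = srna.secondary_fraction(profiles, dep_map, self.config)
                    self._write(table, "srna_size_by_cleavage.tsv")
                # competence needs RNA-seq + ddm1 21-22 nt siRNA + cleavage
                if "rnaseq" in self.paths and "active" in getattr(self, "dependency", {}):
                    rnaseq = pd.read_csv(self.paths["rnaseq"], sep="\t")
                    rna = dict(zip(rnaseq["feature_id"], rnaseq["rpm"]))
                    ddm1_libs = {p.library_id for p in profiles
                                 if "ddm1" in p.library_id
                                 and "rdr6" not in p.library_id}
                    sirna = {}
                    for p in profiles:
                        if p.library_id in ddm1_libs:
                            sirna[p.feature_id] = sirna.get(p.feature_id, 0.0) + \
                                p.rpm_in(self.config.secondary_sizes)
                    dep = self.dependency["active"]["dependency"]
                    rows = []
                    for f in self.tes:
                        call = srna.competence(
                            f.id, rna.get(f.id, 0.0), sirna.get(f.id, 0.0),
                            dep.get(f.id, "UNCLEAVED") != "UNCLEAVED",
                            self.config)
                        rows.append((f.id, call.competent,
                                     "|".join(sorted(call.evidence))))
                    comp = pd.DataFrame(rows, columns=["feature_id", "competent",
                                                       "evidence"]
                                        ).set_index("feature_id")
                    self._write(comp, "competence.tsv")
                    self.competence = comp

        with self._stage("report"):
            self._write(self.report(), "report.tsv", index=False)

        self._write_run_record()
        return self.out

    def report(self) -> pd.DataFrame:
        """Category counts per background plus the active/silent count ratio
        (NaN where the silent count is zero)."""
        rows = []
        for cat in classifier.CATEGORIES:
            n_s = int(self.counts["silent"].get(cat, 0)) if "silent" in self.counts else 0
            n_a = int(self.counts["active"].get(cat, 0)) if "active" in self.counts else 0
            ratio = n_a / n_s if ("active" in self.counts and n_s > 0) else np.nan
            rows.append((cat, n_s, n_a, ratio))
        return pd.DataFrame(rows, columns=["category", "n_silent", "n_active",
                                           "active_over_silent"])

    def _write_run_record(self) -> None:
        record = {
            "seed": self.seed,
            "config_snapshot": self.run_cfg,
            "pipeline_config": dataclasses.asdict(self.config),
            "input_checksums": {k: _sha256(p) for k, p in sorted(self.paths.items())
                                if p.is_file()},
            "output_manifest": {p.name: _sha256(p)
                                for p in sorted(set(self.outputs))},
            "stage_timings_s": self.timings,
            "warnings": self.warnings,
        }
        with open(self.out / "run_record.json", "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True, default=str)


def run_all(config_path, out_dir) -> Path:
    """Run every stage the configuration enables; returns the output directory."""
    return PipelineRun(config_path, out_dir).run()


def output_checksums(out_dir) -> dict[str, str]:
    """The output manifest of a finished run (file name -> sha256)."""
    with open(Path(out_dir) / "run_record.json") as fh:
        return json.load(fh)["output_manifest"]
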
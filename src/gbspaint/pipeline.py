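"""End-to-end pipeline: simulate-or-ingest through E-painting.

A single YAML configuration drives the whole analysis: per-sample tag-count
tables (read from a manifest or simulated), sample validation by Dice/PCoA
outlier screening, species-level merging and ploidy normalization,
catalogue scoring with Table-1-style summary statistics, de novo key-tag
ordination, in silico polyploids, and map-based chromosome E-painting with
Circos-compatible exports.  Stages communicate through files in the output
directory, every stochastic step draws a named substream of the master
seed, and a run log records parameters and input hashes so any output can
be reproduced.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import epaint, insilico, keytags, ordination, scoring, simulate, tagcounts

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline"]

log = logging.getLogger("gbspaint")

DEFAULT_PARAMS: dict[str, Any] = {
    "min_count": 1,
    "keytag_lo": 20,
    "keytag_hi": 50,
    "window": 30.0,
    "step": 1.0,
    "pct_diploid": epaint.DIPLOID_PCT,
    "pct_tetraploid": epaint.TETRAPLOID_PCT,
    "min_frac": 0.15,
    "k_mad": 3.0,
    "pcoa_axes": 2,
}


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration.

    Either ``simulate`` holds synthetic-study settings (the bundled default
    study), or ``catalog``/``map``/``manifest`` point at real inputs.  The
    manifest lists per-sample entries (sample, path, species, ploidy,
    group); ``groups`` names the ancestral reference groups used for the in
    silico pairing rule and the E-painting tracks.
    """

    seed: int = 0
    output_dir: Path = Path("gbspaint_out")
    simulate: dict[str, Any] | None = None
    catalog: Path | None = None
    map: Path | None = None
    manifest: list[dict[str, Any]] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)
    upsample: list[str] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)

    def param(self, name: str):
        return self.params.get(name, DEFAULT_PARAMS[name])


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "gbspaint_out")),
        simulate=raw.get("simulate"),
        catalog=Path(raw["catalog"]) if raw.get("catalog") else None,
        map=Path(raw["map"]) if raw.get("map") else None,
        manifest=list(raw.get("manifest", [])),
        groups={k: list(v) for k, v in (raw.get("groups") or {}).items()},
        upsample=list(raw.get("upsample", [])),
        params=dict(raw.get("params", {})),
    )
    return cfg


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Cross-check a configuration; returns an itemized list of errors."""
    errors: list[str] = []
    if cfg.simulate is None:
        if cfg.catalog is None or not cfg.catalog.exists():
            errors.append(f"catalog file missing: {cfg.catalog}")
        if cfg.map is None or not cfg.map.exists():
            errors.append(f"map file missing: {cfg.map}")
        if not cfg.manifest:
            errors.append("manifest is empty and no simulation block given")
        species_seen: set[str] = set()
        for entry in cfg.manifest:
            sample = entry.get("sample", "<unnamed>")
            path = entry.get("path")
            if not path or not Path(path).exists():
                errors.append(f"sample {sample}: tag-count file missing: {path}")
            ploidy = entry.get("ploidy")
            if ploidy not in (2, 4, 6):
                errors.append(f"sample {sample}: ploidy must be 2, 4 or 6, got {ploidy}")
            if not entry.get("species"):
                errors.append(f"sample {sample}: no species label")
            else:
                species_seen.add(entry["species"])
        for group, members in cfg.groups.items():
            for m in members:
                if m not in species_seen:
                    errors.append(f"group {group}: unknown species {m!r}")
    else:
        for key in ("n_loci", "samples_per_species"):
            val = cfg.simulate.get(key)
            if val is not None and (not isinstance(val, int) or val < 1):
                errors.append(f"simulate.{key} must be a positive integer")
    lo, hi = cfg.param("keytag_lo"), cfg.param("keytag_hi")
    if not (1 <= lo <= hi):
        errors.append(f"key-tag window [{lo}, {hi}] invalid")
    for name in ("pct_diploid", "pct_tetraploid"):
        if not 0 < cfg.param(name) < 100:
            errors.append(f"{name} must be in (0, 100)")
    if not errors:
        counts: dict[str, int] = {}
        for entry in cfg.manifest:
            counts[entry["species"]] = counts.get(entry["species"], 0) + 1
        for sp, n in sorted(counts.items()):
            log.info("species %s: %d sample(s)", sp, n)
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulated_inputs(cfg: PipelineConfig, outdir: Path):
    """Build the synthetic study described by the config's simulate block."""
    sim = dict(cfg.simulate or {})
    model_kwargs = {}
    if "n_loci" in sim:
        model_kwargs["n_loci"] = int(sim["n_loci"])
    model = simulate.default_model(**model_kwargs)
    ref = simulate.simulate_reference_model(model, cfg.seed)
    simulate.write_reference(ref, outdir / "reference")
    species = simulate.study_species()
    n_samples = int(sim.get("samples_per_species", 3))
    manifest: list[dict[str, Any]] = []
    sample_dir = outdir / "samples"
    sample_dir.mkdir(parents=True, exist_ok=True)
    for spec in species:
        for table in simulate.simulate_cohort(ref, spec, n_samples, cfg.seed):
            path = sample_dir / f"{table.label}.tsv"
            tagcounts.write_tagcounts(table, path)
            manifest.append({"sample": table.label, "path": str(path),
                             "species": spec.name, "ploidy": spec.ploidy})
    spec_by_name = {s.name: s for s in species}
    for entry in sim.get("misclassified", []):
        cohort = spec_by_name[entry["cohort"]]
        wrong = spec_by_name[entry["wrong"]]
        table, flag = simulate.inject_misclassified_sample(ref, cohort, wrong, cfg.seed)
        path = sample_dir / f"{table.label}.tsv"
        tagcounts.write_tagcounts(table, path)
        manifest.append({"sample": table.label, "path": str(path),
                         "species": cohort.name, "ploidy": cohort.ploidy})
    groups = cfg.groups or {
        "A_diploid": ["A_dip_1", "A_dip_2"],
        "C_diploid": ["C_dip_1", "C_dip_2"],
        "DC_tetraploid": ["DC_tet_1", "DC_tet_2"],
        "hexaploid": ["ACD_hex"],
    }
    return ref.catalog, ref.cmap, manifest, groups


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict[str, Any]:
    """Run every stage; returns a summary dict (also written as run_log.yaml).

    With ``resume=True`` a completed run (its run_log.yaml already present
    in the output directory) is not recomputed; the recorded log is
    returned, so a batch of runs can be restarted after interruption.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    out = cfg.output_dir
    if resume and (out / "run_log.yaml").exists():
        log.info("resume: %s already complete", out)
        return yaml.safe_load((out / "run_log.yaml").read_text(encoding="utf-8"))
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict[str, Any] = {"seed": cfg.seed, "params": {
        k: cfg.param(k) for k in DEFAULT_PARAMS}, "stages": {}}

    # -- stage: inputs -----------------------------------------------------
    if cfg.simulate is not None:
        catalog, cmap, manifest, groups = _simulated_inputs(cfg, out)
    else:
        catalog = scoring.read_catalog(cfg.catalog)
        cmap = epaint.read_map(cfg.map)
        manifest, groups = cfg.manifest, cfg.groups
    sample_tables = {e["sample"]: tagcounts.read_tagcounts(Path(e["path"]))
                     for e in manifest}
    for e in manifest:  # manifest metadata wins over file headers
        t = sample_tables[e["sample"]]
        sample_tables[e["sample"]] = t.relabel(e["sample"], ploidy=e["ploidy"])
    run_log["stages"]["inputs"] = {
        "n_samples": len(sample_tables),
        "catalog_loci": catalog.n_loci,
        "catalog_tags": catalog.n_tags,
        "input_hashes": {e["sample"]: _sha256(Path(e["path"])) for e in manifest},
    }
    log.info("inputs: %d samples, %d catalogue loci", len(sample_tables), catalog.n_loci)

    # -- stage: sample validation -----------------------------------------
    calls = scoring.score_tables(catalog, list(sample_tables.values()),
                                 min_count=cfg.param("min_count"))
    calls.text.to_csv(out / "calls_samples.tsv", sep="\t")
    dist_samples = ordination.dice_matrix(calls.binary)
    ordination.write_distance(dist_samples, out / "dist_samples.tsv")
    cohorts = {e["sample"]: e["species"] for e in manifest}
    flagged = ordination.flag_outliers(dist_samples, cohorts, k_mad=cfg.param("k_mad"))
    (out / "flagged_samples.txt").write_text("\n".join(flagged) + ("\n" if flagged else ""),
                                             encoding="utf-8")
    ord_samples = ordination.pcoa(dist_samples, k=cfg.param("pcoa_axes"))
    ordination.write_ordination(ord_samples, out / "pcoa_samples.tsv")
    run_log["stages"]["validation"] = {"flagged": flagged}
    log.info("validation: %d sample(s) flagged as outliers", len(flagged))

    # -- stage: species merge + normalization ------------------------------
    by_species: dict[str, list] = {}
    for e in manifest:
        if e["sample"] in flagged:
            continue
        by_species.setdefault(e["species"], []).append(sample_tables[e["sample"]])
    species_tables = []
    for sp, tabs in by_species.items():
        merged = tagcounts.merge_tagcounts(tabs, label=sp)
        merged.ploidy = tabs[0].ploidy
        species_tables.append(merged)
    normalized, plan = tagcounts.normalize_by_ploidy(
        species_tables, seed=cfg.seed, upsample_labels=cfg.upsample)
    norm_dir = out / "normalized"
    norm_dir.mkdir(exist_ok=True)
    for t in normalized:
        tagcounts.write_tagcounts(t, norm_dir / f"{t.label}.tsv")
    run_log["stages"]["normalize"] = {
        "unit": plan.unit, "targets": plan.targets,
        "totals": {t.label: t.total for t in normalized},
        "upsampled": sorted(plan.upsampled),
    }
    log.info("normalize: 1x unit = %d tags", plan.unit)
    norm_by_label = {t.label: t for t in normalized}

    # -- stage: species-level catalogue scoring ----------------------------
    sp_calls = scoring.score_tables(catalog, normalized, min_count=cfg.param("min_count"))
    sp_calls.text.to_csv(out / "calls_species.tsv", sep="\t")
    stats_rows = []
    for sp in sp_calls.samples:
        st = scoring.shared_stats(sp_calls.row(sp), catalog)
        stats_rows.append((sp, st.pct_loci_present, st.haplotypes_per_shared_locus))
    with (out / "stats_species.tsv").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("species\tpct_loci_present\thaplotypes_per_shared_locus\n")
        for sp, pct, ratio in stats_rows:
            fh.write(f"{sp}\t{pct:.4f}\t{ratio:.4f}\n")
    run_log["stages"]["scoring"] = {
        sp: {"pct": round(p, 4)} for sp, p, _ in stats_rows}

    # -- stage: de novo key tags -------------------------------------------
    keyset = keytags.select_key_tags(normalized, lo=cfg.param("keytag_lo"),
                                     hi=cfg.param("keytag_hi"), seed=cfg.seed)
    (out / "keytags.txt").write_text("\n".join(keyset.union) + "\n", encoding="utf-8")
    pm = keytags.presence_matrix(keyset, normalized)
    pm.to_csv(out / "presence_denovo.tsv", sep="\t")
    dist_denovo = ordination.dice_matrix(pm)
    ordination.write_distance(dist_denovo, out / "dist_denovo.tsv")
    ordination.write_ordination(ordination.pcoa(dist_denovo, k=cfg.param("pcoa_axes")),
                                out / "pcoa_denovo.tsv")
    (out / "upgma_denovo.nwk").write_text(ordination.upgma(dist_denovo).newick() + "\n",
                                          encoding="utf-8")
    run_log["stages"]["denovo"] = {
        "truncation_size": keyset.truncation_size, "union_size": len(keyset.union)}
    log.info("denovo: %d key tags (truncated to %d per species)",
             len(keyset.union), keyset.truncation_size)

    # -- stage: in silico polyploids ---------------------------------------
    insilico_log: dict[str, Any] = {}
    dip_groups = [g for g in groups if any(
        norm_by_label.get(m) and norm_by_label[m].ploidy == 2 for m in groups[g])]
    tet_groups = [g for g in groups if any(
        norm_by_label.get(m) and norm_by_label[m].ploidy == 4 for m in groups[g])]
    if dip_groups and tet_groups:
        pairing = [(d, t) for d in dip_groups for t in tet_groups]
        combos = insilico.enumerate_combos(groups, pairing, scheme="hexaploid")
        insilico.write_combo_manifest(combos, out / "insilico_combos.tsv")
        pm_is, dist_is, ord_is, tree_is = insilico.insilico_analysis(
            combos, norm_by_label, keyset, axes=cfg.param("pcoa_axes"))
        ordination.write_distance(dist_is, out / "dist_insilico.tsv")
        ordination.write_ordination(ord_is, out / "pcoa_insilico.tsv")
        (out / "upgma_insilico.nwk").write_text(tree_is.newick() + "\n", encoding="utf-8")
        insilico_log["n_combos"] = len(combos)
        log.info("insilico: %d combinations", len(combos))
    run_log["stages"]["insilico"] = insilico_log

    # -- stage: chromosome E-painting --------------------------------------
    epaint_log: dict[str, Any] = {}
    track_groups = {"A": "A_diploid", "C": "C_diploid", "DC": "DC_tetraploid"}
    if all(g in groups for g in track_groups.values()):
        mapped = catalog.mapped()
        group_tables = []
        for gname, members in groups.items():
            tabs = [norm_by_label[m] for m in members if m in norm_by_label]
            if not tabs:
                continue
            gt = tagcounts.merge_tagcounts(tabs, label=gname)
            group_tables.append(gt)
        profiles: dict[str, epaint.WindowProfile] = {}
        prof_frames = []
        for gt in group_tables:
            row = scoring.score_sample(mapped, gt, min_count=cfg.param("min_count"))
            prof = epaint.window_profiles(row, cmap, window=cfg.param("window"),
                                          step=cfg.param("step"), group=gt.label)
            profiles[gt.label] = prof
            frame = prof.table.copy()
            frame.insert(0, "group", gt.label)
            prof_frames.append(frame)
        pd.concat(prof_frames).to_csv(out / "profiles.tsv", sep="\t", index=False)
        pct = {"A_diploid": cfg.param("pct_diploid"),
               "C_diploid": cfg.param("pct_diploid"),
               "DC_tetraploid": cfg.param("pct_tetraploid")}
        tracks = {
            key: epaint.percentile_paint(profiles[gname], pct[gname])
            for key, gname in track_groups.items()
        }
        assignment = epaint.assign_genomes(
            tracks["A"], tracks["C"], tracks["DC"], profiles, cmap,
            min_frac=cfg.param("min_frac"))
        epaint.write_segments(assignment, out / "segments.tsv")
        epaint.write_assignment_summary(assignment, out / "assignment.tsv")
        epaint.export_circos(cmap, list(tracks.values()), out / "circos",
                             assignment=assignment)
        epaint_log["primary"] = dict(assignment.primary)
        log.info("epaint: assigned %d chromosomes", len(assignment.primary))
    run_log["stages"]["epaint"] = epaint_log

    with (out / "run_log.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=False)
    return run_log
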
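"""End-to-end pipeline: filter -> diversity -> ROH/LD -> structure ->
demography -> load, driven by one YAML-able config with a global seed.

Every stage writes its artifacts into the output directory and records them
in a JSON manifest (SHA-256 per output, stage parameters, stage seed).
Stage seeds are split deterministically from the global seed by stage name,
so enabling or disabling one stage never changes another's randomness.
Stage outputs are pure functions of (inputs, parameters, seed): rerunning
an identical config reproduces identical manifests for deterministic
stages.  A stage whose inputs are absent (e.g. no gene models for the load
stage) is skipped with a logged reason; a stage failure halts the run with
the stage name and a partial manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import demography, diversity, filtering, io, roh, structure, synthetic
from . import load as load_mod

logger = logging.getLogger("declinescan")

STAGES = ("filter", "diversity", "roh_ld", "structure", "demography", "load")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths: vcf, sample_sheet, scaffold_lengths,
    and optionally gene_models, reference_fasta, mtdna_fasta) or
    ``synthetic`` (a scenario block for the built-in generators) must be
    present.  ``seed`` must be set explicitly.
    """

    out_dir: Path
    seed: int
    inputs: dict[str, str] | None = None
    synthetic: dict[str, Any] | None = None
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return PipelineConfig.from_dict(raw, base=Path(path).parent)

    @staticmethod
    def from_dict(raw: Mapping[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("config must set 'seed' explicitly")
        has_inputs = bool(raw.get("inputs"))
        has_synth = bool(raw.get("synthetic"))
        if has_inputs == has_synth:
            raise ValueError("config must have exactly one of 'inputs' or 'synthetic'")
        return PipelineConfig(
            out_dir=base / raw.get("out_dir", "declinescan_out"),
            seed=int(raw["seed"]),
            inputs=raw.get("inputs"),
            synthetic=raw.get("synthetic"),
            params={k: dict(v) for k, v in (raw.get("params") or {}).items()},
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with the stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, outputs: dict[str, Path], params: Mapping[str, Any],
               skipped: str | None = None) -> None:
        entry: dict[str, Any] = {"seed": stage_seed(config.seed, stage),
                                 "params": dict(params)}
        if skipped:
            entry["skipped"] = skipped
        else:
            entry["outputs"] = {name: {"path": str(p.relative_to(out)),
                                       "sha256": _sha256(p)}
                                for name, p in outputs.items()}
        manifest["stages"][stage] = entry
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    # ---- inputs -----------------------------------------------------------
    try:
        if config.synthetic is not None:
            gm, sheet, lengths, genes, ref_seqs, derived = _generate_inputs(
                config.synthetic, stage_seed(config.seed, "simulate"), out)
            sim_outputs = {
                "vcf": out / "synthetic.vcf",
                "sample_sheet": out / "samples.tsv",
                "scaffold_lengths": out / "scaffolds.tsv",
            }
            io.write_vcf(gm, sim_outputs["vcf"], lengths)
            io.write_sample_sheet(sheet, sim_outputs["sample_sheet"])
            io.write_scaffold_lengths(lengths, sim_outputs["scaffold_lengths"])
            if genes:
                sim_outputs["gene_models"] = out / "genes.gff3"
                io.write_gene_models(genes, sim_outputs["gene_models"])
                sim_outputs["reference"] = out / "reference.fa"
                io.write_fasta(ref_seqs, sim_outputs["reference"])
            record("simulate", sim_outputs, config.synthetic)
        else:
            paths = config.inputs
            gm = io.read_vcf(paths["vcf"])
            sheet = io.read_sample_sheet(paths["sample_sheet"])
            lengths = io.read_scaffold_lengths(paths["scaffold_lengths"])
            genes = (io.read_gene_models(paths["gene_models"])
                     if paths.get("gene_models") else None)
            ref_seqs = (io.read_fasta(paths["reference_fasta"])
                        if paths.get("reference_fasta") else None)
            derived = None
    except Exception as exc:  # noqa: BLE001 - halt with stage name
        raise StageFailure("inputs", exc) from exc

    # ---- filter -----------------------------------------------------------
    stage = "filter"
    try:
        p = config.params.get(stage, {})
        if gm.has_depths:
            filtered, report = filtering.run_filters(
                gm, lengths,
                min_length=int(p.get("min_scaffold_length", 100_000)),
                excluded_labels=set(p.get("excluded_scaffolds", ())),
                min_phred=float(p.get("min_phred", 20.0)),
                min_fraction=float(p.get("min_allele_fraction", 0.20)),
            )
        else:
            report = filtering.FilterReport(input_sites=gm.n_sites)
            filtered = filtering.filter_scaffolds(
                gm, lengths, int(p.get("min_scaffold_length", 100_000)),
                set(p.get("excluded_scaffolds", ())), report)
            filtered = filtering.filter_quality(
                filtered, float(p.get("min_phred", 20.0)), report)
            report.surviving_sites = filtered.n_sites
        vcf_path = out / "filtered.vcf"
        rep_path = out / "filter_report.json"
        io.write_vcf(filtered, vcf_path, lengths)
        report.to_json(rep_path)
        record(stage, {"vcf": vcf_path, "report": rep_path}, p)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- diversity --------------------------------------------------------
    stage = "diversity"
    try:
        p = config.params.get(stage, {})
        windows = diversity.windowed_heterozygosity(
            filtered, int(p.get("window_bp", 50_000)), lengths)
        summary = diversity.population_mean_he(windows, sheet)
        wpath = out / "heterozygosity_windows.tsv"
        spath = out / "heterozygosity_summary.tsv"
        windows.to_csv(wpath, sep="\t", index=False)
        summary.to_csv(spath, sep="\t", index=False)
        record(stage, {"windows": wpath, "summary": spath}, p)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- roh_ld -----------------------------------------------------------
    stage = "roh_ld"
    try:
        p = config.params.get(stage, {})
        segments = roh.detect_roh(
            filtered,
            min_length_bp=int(p.get("min_length_bp", 10_000)),
            max_het=int(p.get("max_het", 0)),
            snp_count=int(p.get("snp_count", 20)),
            snp_rule=p.get("snp_rule", "min"),
        )
        genome_bp = sum(lengths.values())
        summary = roh.summarize_roh(segments, genome_bp, sheet)
        curve, decay = roh.ld_decay(filtered,
                                    max_dist_bp=int(p.get("ld_max_dist_bp", 100_000)),
                                    n_bins=int(p.get("ld_bins", 20)))
        rpath = out / "roh_segments.tsv"
        supath = out / "roh_summary.tsv"
        lpath = out / "ld_curve.tsv"
        segments.to_csv(rpath, sep="\t", index=False)
        summary.to_csv(supath, sep="\t", index=False)
        curve.assign(decay_bin_bp=decay).to_csv(lpath, sep="\t", index=False)
        record(stage, {"segments": rpath, "summary": supath, "ld_curve": lpath}, p)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- structure --------------------------------------------------------
    stage = "structure"
    try:
        p = config.params.get(stage, {})
        thin_idx = roh.ld_thin(filtered, float(p.get("thin_r2", 0.5)),
                               int(p.get("thin_window_bp", 50_000)))
        thinned = filtered.take_sites(thin_idx)
        pca = structure.pca_genotypes(thinned,
                                      n_axes=int(p.get("n_axes", 4)))
        ppath = out / "pca_coordinates.tsv"
        epath = out / "pca_eigen.tsv"
        pca.coordinates.to_csv(ppath, sep="\t")
        pd.DataFrame({
            "eigenvalue": pca.eigenvalues[:len(pca.tw_stats)],
            "tw_stat": pca.tw_stats, "tw_p": pca.tw_pvalues,
        }).to_csv(epath, sep="\t", index=False)
        outputs = {"pca": ppath, "eigen": epath}
        dos = pd.DataFrame(thinned.dosage(), columns=thinned.samples)
        if thinned.n_sites >= 10 and thinned.n_samples >= 3:
            tree, support = structure.bootstrap_support(
                dos, n_reps=int(p.get("bootstrap_reps", 100)),
                seed=stage_seed(config.seed, stage))
            tpath = out / "nj_tree.nwk"
            tree.write(str(tpath))
            outputs["tree"] = tpath
        record(stage, outputs, p)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- demography -------------------------------------------------------
    stage = "demography"
    try:
        p = config.params.get(stage, {})
        pops = sorted(sheet["population"].unique())
        if len(pops) < 2:
            record(stage, {}, p, skipped="needs two populations")
        else:
            a = sheet.loc[sheet["population"] == pops[0], "sample"].tolist()
            b = sheet.loc[sheet["population"] == pops[1], "sample"].tolist()
            gm1 = filtered.subset_samples(a)
            gm2 = filtered.subset_samples(b)
            if derived is not None:
                sfs = demography.truth_polarized_sfs(
                    gm1, gm2, sequence_length_bp=sum(lengths.values()))
            else:
                sfs, _ = demography.polarize_joint_sfs(
                    gm1, gm2, filtered,
                    sequence_length_bp=sum(lengths.values()))
            spath = out / "joint_sfs.tsv"
            sfs.to_tsv(spath)
            model = demography.split_model_template(
                mutation_rate=float(p.get("mutation_rate", 1.47e-8)))
            fit = demography.fit_model(
                sfs, model, {"pop1": len(a), "pop2": len(b)},
                n_sims_per_eval=int(p.get("n_sims_per_eval", 150)),
                n_starts=int(p.get("n_starts", 2)),
                max_cycles=int(p.get("max_cycles", 10)),
                medium_factor=int(p.get("medium_factor", 3)),
                polish_factor=int(p.get("polish_factor", 1)),
                seed=stage_seed(config.seed, stage))
            fpath = out / "demography_fit.json"
            with open(fpath, "w") as fh:
                json.dump(fit.to_json_dict(), fh, indent=2)
            record(stage, {"sfs": spath, "fit": fpath}, p)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- load -------------------------------------------------------------
    stage = "load"
    try:
        p = config.params.get(stage, {})
        if not genes or ref_seqs is None:
            logger.info("load stage skipped: no gene models configured")
            record(stage, {}, p, skipped="no gene models / reference provided")
        else:
            annotated = load_mod.annotate_variants(filtered, genes, ref_seqs)
            apath = out / "annotated_variants.tsv"
            annotated.to_csv(apath, sep="\t", index=False)
            outputs = {"annotated": apath}
            if derived is not None and len(derived):
                key = pd.MultiIndex.from_frame(
                    filtered.sites[["scaffold", "pos"]])
                dkey = pd.MultiIndex.from_frame(derived[["scaffold", "pos"]])
                locs = key.get_indexer(dkey)
                ok = locs >= 0
                summary_rows = []
                for cls in ("missense", "nonsense", "splice_disrupting"):
                    hits = annotated[annotated["effect"] == cls]
                    hit_idx = [i for i in hits["site_index"] if i in set(locs[ok])]
                    if not hit_idx:
                        continue
                    pos_of = dict(zip(locs[ok], derived.loc[ok, "ancestral_is_ref"]))
                    lr = load_mod.load_ratio(
                        filtered, hit_idx, [pos_of[i] for i in hit_idx])
                    lr["category"] = cls
                    summary_rows.append(lr)
                if summary_rows:
                    lpath = out / "load_summary.tsv"
                    pd.concat(summary_rows).to_csv(lpath, sep="\t", index=False)
                    outputs["load_summary"] = lpath
            record(stage, outputs, p)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    return manifest


def _generate_inputs(block: Mapping[str, Any], seed: int, out: Path):
    """Materialize a synthetic scenario block into pipeline inputs."""
    kind = block.get("kind", "coalescent")
    genes = None
    ref_seqs = None
    derived = None
    if kind == "coalescent":
        ne = float(block.get("ne", 5000))
        t_split = float(block.get("t_split", 2000))
        m = float(block.get("migration", 0.0))
        n_per_pop = int(block.get("n_per_pop", 4))
        n_loci = int(block.get("n_loci", 50))
        locus_length = int(block.get("locus_length_bp", 50_000))
        spec = synthetic.PopulationModelSpec.two_population_split(
            ne, ne, ne, t_split, m12=m, m21=m)
        gm = synthetic.simulate_coalescent(
            spec, {"pop1": n_per_pop, "pop2": n_per_pop}, n_loci,
            locus_length, seed)
        if block.get("noise", True):
            gm = synthetic.add_sequencing_noise(
                gm, synthetic.NoiseSpec(), seed + 1)
        sheet = pd.DataFrame({
            "sample": gm.samples,
            "species": ["sp1"] * len(gm.samples),
            "population": [s.split("_")[0] for s in gm.samples],
        })
        lengths = {sc: locus_length for sc in dict.fromkeys(gm.sites["scaffold"])}
    elif kind == "pedigree":
        g = int(block.get("g_loop", 3))
        spec = synthetic.PedigreeSpec.consanguineous_loop(
            g, chromosome_count=int(block.get("chromosomes", 1)),
            map_length_cM=float(block.get("map_length_cM", 100.0)))
        gm, ibd = synthetic.simulate_pedigree(spec, g, seed)
        ibd.to_csv(out / "true_ibd.tsv", sep="\t", index=False)
        sheet = pd.DataFrame({
            "sample": gm.samples,
            "species": ["sp1"] * len(gm.samples),
            "population": ["ped"] * len(gm.samples),
        })
        bp = int(spec.map_length_cM[0] / spec.cM_per_Mb * 1e6)
        lengths = {f"chr{c+1}": bp for c in range(spec.chromosome_count)}
    else:
        raise ValueError(f"unknown synthetic scenario kind {kind!r}")
    if block.get("gene_models"):
        gb = block["gene_models"]
        genes, ref_seqs, planted = synthetic.simulate_gene_models(
            int(gb.get("n_genes", 4)), int(gb.get("cds_length_codons", 30)),
            [(e, int(c)) for e, c in gb.get("plan", [["missense", 4]])],
            seed + 2)
    return gm, sheet, lengths, genes, ref_seqs, derived
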
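"""End-to-end orchestration: simulate → morphometrics → BLUP → variants →
GWAS → cytometry → report, as one reproducible run with a manifest.

Every stage writes its outputs under the run directory and records a SHA-256
checksum in the manifest; re-running with the same config reproduces
identical checksums. A stage failure aborts the run with the stage name and
the partial manifest on disk.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from samgwas import __version__
from samgwas.config import SimConfig
from samgwas import assoc_stats, blup, cytometry, gwas, morphometrics, synthgen, variants

__all__ = ["RunManifest", "run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict[str, Any]
    config_hash: str
    version: str = __version__
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: SimConfig, out_dir: str | Path, make_plots: bool = True) -> RunManifest:
    """Execute the full chain on synthetic data and write a report.

    Outputs under ``out_dir``: contour/phenotype/BLUP tables, VCF, per-SNP
    scan results, TAS and candidate tables, burden correlation, cytometry
    ANOVA tables, morphospace and Manhattan plots, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    manifest = RunManifest(
        config=cfg_dict,
        config_hash=hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
    )

    def checkpoint(stage: str, t0: float, files: list[Path]) -> None:
        manifest.stages[stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for f in files:
            manifest.outputs[str(f.relative_to(out))] = _sha256(f)
        manifest.to_json(out / "manifest.json")

    report: dict[str, Any] = {}

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        geno = synthgen.gen_genotypes(cfg)
        contours, truth = synthgen.gen_contours(cfg, geno=geno)
        vcf_path = out / "genotypes.vcf"
        variants.write_vcf(geno, vcf_path)
        contours_path = out / "contours.tsv"
        morphometrics.write_contours_tsv(contours, contours_path)
        truth_path = out / "truth.json"
        truth.to_json(truth_path)
        genes = synthgen.gen_genes(cfg)
        genes_path = out / "genes.bed"
        synthgen.write_genes_bed(genes, genes_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    checkpoint("simulate", t0, [vcf_path, contours_path, truth_path, genes_path])

    # --- morphometrics ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        fits = {(c.genotype, c.replicate): morphometrics.fit_parabola(c) for c in contours}
        pheno_table = morphometrics.microphenotype_table(fits)
        pheno_path = out / "microphenotypes.tsv"
        pheno_table.to_csv(pheno_path, sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("morphometrics", e) from e
    checkpoint("morphometrics", t0, [pheno_path])

    # --- blup -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        traits = ["height", "radius", "volume"]
        blup_df, components = blup.blup_table(pheno_table, traits)
        blup_path = out / "blups.tsv"
        blup_df.to_csv(blup_path, sep="\t")
        comp_path = out / "variance_components.json"
        comp_path.write_text(json.dumps(components, indent=1))
        report["repeatability_volume"] = components["volume"]["repeatability"]
    except Exception as e:  # noqa: BLE001
        raise StageError("blup", e) from e
    checkpoint("blup", t0, [blup_path, comp_path])

    # --- variants (RNAseq-style calling on a small simulated region) -----
    t0 = time.perf_counter()
    try:
        rna_matrix = _rnaseq_calling_stage(cfg, out)
        combined = variants.concat_sources([geno, rna_matrix]) if rna_matrix.n_sites else geno
        log: dict[str, int] = {}
        filtered = variants.filter_matrix(combined, log=log)
        stats_path = out / "site_stats.tsv"
        variants.site_stats_table(filtered).to_csv(stats_path, sep="\t", index=False)
        report["variant_filter"] = log
    except Exception as e:  # noqa: BLE001
        raise StageError("variants", e) from e
    checkpoint("variants", t0, [stats_path])

    # --- gwas -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        y = blup_df["volume"].reindex(filtered.individuals).to_numpy()
        K = gwas.kinship(filtered)
        pcs = gwas.genotype_pcs(filtered, n_pcs=3)
        n_pcs, bics = gwas.select_model(y, K, pcs, max_pcs=3)
        covs = pcs[:, :n_pcs] if n_pcs else None
        scan = gwas.mlm_scan(y, filtered, K, covariates=covs, alpha=0.01)
        scan_path = out / "gwas_results.tsv"
        scan.table.to_csv(scan_path, sep="\t", index=False)
        tas = gwas.call_tas(scan, filtered)
        tas = gwas.map_candidates(tas, genes, window=100_000)
        tas_rows = [
            {
                "chrom": t.chrom, "pos": t.pos, "com": t.com, "alt": t.alt,
                "neglog10p": t.neglog10p,
                "genes": ";".join(f"{g}:{d}:{'in' if inside else 'near'}" for g, d, inside in t.genes),
            }
            for t in tas
        ]
        tas_path = out / "tas.tsv"
        pd.DataFrame(tas_rows, columns=["chrom", "pos", "com", "alt", "neglog10p", "genes"]).to_csv(
            tas_path, sep="\t", index=False
        )
        report["gwas"] = {
            "m_tested": scan.m_tested,
            "threshold": scan.threshold,
            "n_pcs": n_pcs,
            "bic": bics,
            "n_tas": len(tas),
        }
        if tas:
            try:
                counts, corr = gwas.alt_burden(tas, filtered, y)
                report["burden"] = {"r": corr.r, "p": corr.p, "n": corr.n}
            except (ValueError, assoc_stats.UndefinedStatisticError) as e:
                report["burden"] = {"error": str(e)}
        sizes = assoc_stats.classify_sizes(blup_df["volume"])
        report["size_classes"] = sizes.counts()
    except Exception as e:  # noqa: BLE001
        raise StageError("gwas", e) from e
    checkpoint("gwas", t0, [scan_path, tas_path])

    # --- cytometry --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        cyto_path = out / "cytometry_anova.tsv"
        report["cytometry"] = _cytometry_stage(cfg, blup_df, tas, filtered, cyto_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("cytometry", e) from e
    checkpoint("cytometry", t0, [cyto_path])

    # --- report -----------------------------------------------------------
    t0 = time.perf_counter()
    files = []
    try:
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, default=float))
        files.append(report_path)
        if make_plots:
            files += _plots(blup_df, scan, out)
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e
    checkpoint("report", t0, files)
    return manifest


def _rnaseq_calling_stage(cfg: SimConfig, out: Path) -> variants.GenotypeMatrix:
    """Simulate reads on a small region for a subset of individuals and call
    SNPs through trim → alignment filter → pileup, producing an
    RNAseq-source matrix on its own contig (no overlap with the genomic
    source)."""
    rng = cfg.rng("reads")
    ref_len = 2000
    bases = "ACGT"
    reference = "".join(bases[i] for i in rng.integers(0, 4, ref_len))
    n_sites = 8
    positions = np.sort(rng.choice(np.arange(200, ref_len - 200), n_sites, replace=False))
    alts = ["ACGT"[(bases.index(reference[p]) + 1) % 4] for p in positions]
    ids = synthgen.genotype_ids(cfg)
    p_alt = rng.uniform(*cfg.alt_freq_range, n_sites)
    carrier = rng.random((len(ids), n_sites)) < p_alt
    calls = np.full((len(ids), n_sites), variants.MISSING, dtype=np.int8)
    for i, gid in enumerate(ids):
        sites_i = [(int(positions[j]), alts[j]) for j in range(n_sites) if carrier[i, j]]
        _, alns = synthgen.gen_reads(
            reference, sites_i, depth=8, seed=int(rng.integers(0, 2**31)),
            chrom="rna1", sample=gid,
        )
        kept = [a for a in alns if variants.filter_alignment(a)]
        piles = variants.pileups_from_alignments(kept, {"rna1": reference})
        for j, p in enumerate(positions):
            pile = piles.get(("rna1", int(p)))
            calls[i, j] = variants.call_site(pile) if pile else variants.MISSING
    sites = pd.DataFrame(
        {"chrom": "rna1", "pos": positions.astype(int), "com": [reference[p] for p in positions], "alt": alts}
    )
    m = variants.GenotypeMatrix(individuals=ids, sites=sites, calls=calls, source="rnaseq")
    variants.write_vcf(m, out / "rnaseq_calls.vcf")
    return m


def _cytometry_stage(cfg, blup_df, tas, geno, out_path: Path) -> dict[str, Any]:
    """Segment and tessellate nuclei images for a small genotype sample and
    run the two-way SCN/ASCS ANOVA against a TAS genotype class."""
    rng = cfg.rng("cytometry-stage")
    n_sample = min(12, len(blup_df))
    chosen = list(blup_df.sort_values("volume").index[:: max(1, len(blup_df) // n_sample)])[:n_sample]
    if tas:
        j = {(t.chrom, t.pos) for t in tas}
        cols = [k for k, (c, p) in enumerate(zip(geno.sites["chrom"], geno.sites["pos"])) if (c, p) in j]
        ind_index = {g: i for i, g in enumerate(geno.individuals)}
        def gclass(g):
            return "ALT" if (geno.calls[ind_index[g], cols] == 2).any() else "COM"
    else:
        def gclass(g):
            return "ALT" if rng.random() < 0.5 else "COM"
    rows = []
    for gid in chosen:
        vol = float(blup_df.loc[gid, "volume"])
        h = float(blup_df.loc[gid, "height"]) if "height" in blup_df else 100.0
        r = float(blup_df.loc[gid, "radius"]) if "radius" in blup_df else 80.0
        cell_area = 60.0 if gclass(gid) == "COM" else 45.0
        img, mask, _ = synthgen.gen_nuclei_image(h, r, cell_area, cfg, rng=rng)
        cents = cytometry.segment_nuclei(img, mask)
        if len(cents) == 0:
            continue
        lattice = cytometry.tessellate(cents, mask)
        rows.append({"genotype_class": gclass(gid), "volume": vol, "scn": lattice.scn, "ascs": lattice.ascs})
    table = pd.DataFrame(rows)
    result: dict[str, Any] = {"n_images": len(table)}
    if len(table) >= 6 and table["genotype_class"].nunique() == 2 and table.groupby("genotype_class").size().min() >= 3:
        anova = cytometry.scn_ascs_model(table, response="scn")
        anova.to_csv(out_path, sep="\t")
        result["scn_anova_p"] = {k: float(v) for k, v in anova["PR(>F)"].dropna().items()}
    else:
        out_path.write_text("insufficient class balance for ANOVA\n")
        result["note"] = "insufficient class balance for ANOVA"
    return result


def _plots(blup_df: pd.DataFrame, scan: gwas.MLMResult, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(blup_df["radius"], blup_df["height"], s=8, alpha=0.6, c=blup_df["volume"], cmap="viridis")
    ax.set_xlabel("SAM radius BLUP+intercept (µm)")
    ax.set_ylabel("SAM height BLUP+intercept (µm)")
    ax.set_title("SAM morphospace")
    p = out / "morphospace.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 3))
    tbl = scan.table
    chroms = list(pd.unique(tbl["chrom"]))
    offset = 0
    for i, c in enumerate(chroms):
        sub = tbl[tbl["chrom"] == c]
        ax.scatter(sub["pos"] + offset, sub["neglog10p"], s=4, color=f"C{i % 2}")
        offset += sub["pos"].max() + 1
    ax.axhline(scan.threshold, ls=":", color="k")
    ax.set_xlabel("genome position")
    ax.set_ylabel("−log10 p")
    ax.set_title(f"Manhattan plot (threshold {scan.threshold:.2f})")
    p = out / "manhattan.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    return paths
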
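"""End-to-end pipeline: simulate/load regions, then blocks, CNS, rates,
dating and an NJ tree, emitting table-shaped TSV reports and a run manifest.

The pipeline is deterministic given the config seed; the manifest records
parameters and SHA-256 checksums of every output so reruns can be diffed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .blocks import BlockParams, classify_gaps, conservation_stats, find_conserved_blocks
from .cns import CNSParams, find_cns, find_ssrs, scan_cis_elements
from .dating import LTR_RATE, Calibration, ltr_insertion_age
from .molevol import (
    SaturationError,
    build_codon_alignment,
    global_align,
    k2p_distance,
    ng86_kaks,
)
from .phylo import DistanceMatrix, bootstrap_support, nj_tree
from .regions import GenomicRegion, read_fasta, read_features, write_features, write_fasta
from .simulate import SimConfig, simulate_lineages


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "syntevol_out"
    lineages: tuple[str, ...] = ("A", "B", "D")
    simulate: dict = field(default_factory=dict)
    inputs: list[dict] = field(default_factory=list)  # [{fasta:, features:}]
    blocks: BlockParams = BlockParams()
    cns: CNSParams = CNSParams()
    ltr_rate: float = LTR_RATE
    calibration: tuple[float, float] = (0.8707, 60.0e6)
    bootstrap: int = 100


_TOP_KEYS = {
    "seed", "out_dir", "lineages", "simulate", "inputs",
    "blocks", "cns", "ltr_rate", "calibration", "bootstrap",
}

_SIM_KEYS = {
    "ancestor_length", "target_K", "ts_tv_ratio", "indel_rate",
    "indel_length_geometric_p", "te_insertions_per_lineage",
    "ancestral_te_count", "ltr_length", "ltr_internal_length",
    "ltr_age_years", "clock_rate_r", "omega_target",
}

_BLOCK_KEYS = {"word_size", "min_identity", "merge_distance", "min_block_length"}
_CNS_KEYS = {"window", "min_identity", "min_length", "genic_mask_padding"}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Schema-check a YAML config (path or pre-parsed mapping), fill defaults,
    and reject unknown keys."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
    lineages = tuple(raw.get("lineages", cfg.lineages))
    if len(set(lineages)) != len(lineages):
        raise ValueError(f"duplicate region id in lineages: {lineages}")
    cfg.lineages = lineages
    sim = raw.get("simulate", {}) or {}
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ValueError(f"unknown simulate keys: {sorted(bad)}")
    cfg.simulate = sim
    cfg.inputs = list(raw.get("inputs", []) or [])
    for entry in cfg.inputs:
        for key in ("fasta", "features"):
            if key not in entry:
                raise ValueError(f"inputs entries need 'fasta' and 'features': {entry}")
            if not Path(entry[key]).exists():
                raise ValueError(f"input file does not exist: {entry[key]}")
    blk = raw.get("blocks", {}) or {}
    bad = set(blk) - _BLOCK_KEYS
    if bad:
        raise ValueError(f"unknown blocks keys: {sorted(bad)}")
    cfg.blocks = BlockParams(**blk)  # BlockParams validates ranges
    cns = raw.get("cns", {}) or {}
    bad = set(cns) - _CNS_KEYS
    if bad:
        raise ValueError(f"unknown cns keys: {sorted(bad)}")
    cfg.cns = CNSParams(**cns)
    cfg.ltr_rate = float(raw.get("ltr_rate", cfg.ltr_rate))
    if cfg.ltr_rate <= 0:
        raise ValueError("ltr_rate must be positive")
    cal = raw.get("calibration", cfg.calibration)
    cfg.calibration = (float(cal[0]), float(cal[1]))
    cfg.bootstrap = int(raw.get("bootstrap", cfg.bootstrap))
    if cfg.bootstrap < 1:
        raise ValueError("bootstrap must be >= 1")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_regions(cfg: PipelineConfig) -> list[GenomicRegion]:
    regions: list[GenomicRegion] = []
    for entry in cfg.inputs:
        for region in read_fasta(entry["fasta"]):
            feats = read_features(entry["features"], dialect=entry.get("dialect", "gff3"))
            region.features = feats.get(region.id, [])
            region.validate_features()
            regions.append(region)
    return regions


def run_pipeline(config: PipelineConfig | str | Path | dict) -> dict:
    """Run simulate -> blocks -> cns -> rates -> dating -> tree; returns the
    manifest (also written to the output directory)."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "inputs"
    try:
        if cfg.inputs:
            regions = _load_regions(cfg)
        else:
            sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulate)
            regions, _truth = simulate_lineages(sim_cfg, cfg.lineages)
            write_fasta(regions, out / "regions.fa")
            write_features(
                {r.id: r.features for r in regions}, out / "regions.gff3", "gff3"
            )
            outputs["regions.fa"] = out / "regions.fa"
            outputs["regions.gff3"] = out / "regions.gff3"

        # ---- conserved blocks / CSR / CFS -------------------------------
        stage = "blocks"
        rows = []
        gap_rows = []
        for ra, rb in combinations(regions, 2):
            blks = find_conserved_blocks(ra, rb, cfg.blocks)
            stats = (
                conservation_stats(blks)
                if blks
                else conservation_stats(blks, overlap_length=min(ra.length, rb.length))
            )
            rows.append(
                {
                    "pair": f"{ra.id}:{rb.id}",
                    "overlap_bp": stats.overlap_length,
                    "conserved_bp": stats.conserved_total,
                    "csr_percent": stats.csr,
                    "n_blocks": stats.n_blocks,
                    "cfs_bp": stats.cfs,
                }
            )
            for ev in classify_gaps(blks, ra, rb):
                gap_rows.append(
                    {
                        "pair": f"{ra.id}:{rb.id}",
                        "side": ev.side,
                        "start": ev.interval[0],
                        "end": ev.interval[1],
                        "cause": ev.cause,
                        "evidence": ",".join(ev.evidence),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "table2_conservation.tsv", sep="\t", index=False)
        outputs["table2_conservation.tsv"] = out / "table2_conservation.tsv"
        pd.DataFrame(
            gap_rows, columns=["pair", "side", "start", "end", "cause", "evidence"]
        ).to_csv(out / "gap_events.tsv", sep="\t", index=False)
        outputs["gap_events.tsv"] = out / "gap_events.tsv"

        # ---- CNS, motifs, SSRs ------------------------------------------
        stage = "cns"
        cns_records = find_cns(regions, cfg.cns)
        for r in regions:
            bed = out / f"cns_{r.id}.bed"
            with bed.open("w") as fh:
                fh.write('track name="CNS"\n')
                for rec in cns_records:
                    s, e = rec.intervals[r.id]
                    fh.write(f"{r.id}\t{s}\t{e}\tCNS|{rec.label}\t0\t+\n")
            outputs[bed.name] = bed
        pd.DataFrame(
            [
                {
                    "label": rec.label,
                    "mean_identity": rec.mean_identity,
                    "min_identity": rec.min_identity,
                    "length_bp": rec.length,
                    **{
                        f"{rid}_interval": f"{s}-{e}"
                        for rid, (s, e) in rec.intervals.items()
                    },
                }
                for rec in cns_records
            ]
        ).to_csv(out / "cns.tsv", sep="\t", index=False)
        outputs["cns.tsv"] = out / "cns.tsv"

        motif_rows = []
        ssr_rows = []
        for r in regions:
            for hit in scan_cis_elements(r.residues):
                motif_rows.append(
                    {"region": r.id, "motif": hit.name, "position": hit.position,
                     "strand": hit.strand}
                )
            for ssr in find_ssrs(r.residues):
                ssr_rows.append(
                    {"region": r.id, "unit": ssr.unit, "copies": ssr.copies,
                     "start": ssr.start, "end": ssr.end}
                )
        pd.DataFrame(motif_rows, columns=["region", "motif", "position", "strand"]).to_csv(
            out / "motifs.tsv", sep="\t", index=False
        )
        pd.DataFrame(ssr_rows, columns=["region", "unit", "copies", "start", "end"]).to_csv(
            out / "ssrs.tsv", sep="\t", index=False
        )
        outputs["motifs.tsv"] = out / "motifs.tsv"
        outputs["ssrs.tsv"] = out / "ssrs.tsv"

        # ---- substitution rates per shared gene -------------------------
        stage = "rates"
        cal = Calibration(*cfg.calibration)
        rate_rows = []
        clock_rows = []
        gene_cds: dict[str, dict[str, str]] = {}
        for r in regions:
            for g in r.features_of_kind("gene"):
                cds = "".join(
                    r.subsequence(f.start, f.end)
                    for f in sorted(r.features_of_kind("CDS"), key=lambda f: f.start)
                    if g.start <= f.start and f.end <= g.end
                )
                if cds:
                    gene_cds.setdefault(g.name, {})[r.id] = cds
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for gene, per_region in sorted(gene_cds.items()):
                for ra, rb in combinations(sorted(per_region), 2):
                    try:
                        ca = build_codon_alignment(per_region[ra], per_region[rb])
                        res = ng86_kaks(ca)
                    except (SaturationError, ValueError):
                        continue
                    rate_rows.append(
                        {
                            "gene": gene,
                            "pair": f"{ra}:{rb}",
                            "n_codons": ca.n_codons,
                            "Ks": round(res.Ks, 4),
                            "Ka": round(res.Ka, 4),
                            "Ka_Ks": None if res.omega is None else round(res.omega, 4),
                            "Ks_full": res.Ks,
                            "Ka_full": res.Ka,
                        }
                    )
                    clock_rows.append(
                        {
                            "gene": gene,
                            "pair": f"{ra}:{rb}",
                            "Ks": res.Ks,
                            "time_mya": round(cal.calibrated_time(res.Ks) / 1e6, 4),
                        }
                    )
        pd.DataFrame(
            rate_rows,
            columns=["gene", "pair", "n_codons", "Ks", "Ka", "Ka_Ks", "Ks_full", "Ka_full"],
        ).to_csv(out / "table3_rates.tsv", sep="\t", index=False)
        pd.DataFrame(clock_rows, columns=["gene", "pair", "Ks", "time_mya"]).to_csv(
            out / "table4_clock.tsv", sep="\t", index=False
        )
        outputs["table3_rates.tsv"] = out / "table3_rates.tsv"
        outputs["table4_clock.tsv"] = out / "table4_clock.tsv"

        # ---- LTR insertion ages ------------------------------------------
        stage = "dating"
        ltr_rows = []
        for r in regions:
            tes = r.features_of_kind("TE")
            l5 = {f.name.rsplit("_LTR5", 1)[0]: f for f in r.features_of_kind("LTR5")}
            l3 = {f.name.rsplit("_LTR3", 1)[0]: f for f in r.features_of_kind("LTR3")}
            for te in tes:
                if te.name not in l5 or te.name not in l3:
                    continue
                try:
                    est = ltr_insertion_age(
                        r.subsequence(l5[te.name].start, l5[te.name].end),
                        r.subsequence(l3[te.name].start, l3[te.name].end),
                        cfg.ltr_rate,
                    )
                except (SaturationError, ValueError):
                    continue
                ltr_rows.append(
                    {
                        "region": r.id,
                        "element": te.name,
                        "K": round(est.K, 4),
                        "age_mya": round(est.mya, 2),
                    }
                )
        pd.DataFrame(ltr_rows, columns=["region", "element", "K", "age_mya"]).to_csv(
            out / "table5_ltr_ages.tsv", sep="\t", index=False
        )
        outputs["table5_ltr_ages.tsv"] = out / "table5_ltr_ages.tsv"

        # ---- NJ tree over the first shared gene ---------------------------
        stage = "phylo"
        tree_file = out / "tree.nwk"
        shared = [
            g for g, per in sorted(gene_cds.items())
            if len(per) == len(regions) and len(regions) >= 3
        ]
        if shared:
            per = gene_cds[shared[0]]
            # protein-guided codon alignment columns across all regions via
            # pairwise alignment to the first region would be heavier; the
            # simulated CDS are gap-free and equal length by construction,
            # otherwise fall back to pairwise global alignment distances.
            lengths = {len(s) for s in per.values()}
            if len(lengths) == 1:
                tree = bootstrap_support(per, n_reps=cfg.bootstrap, seed=cfg.seed)
            else:
                taxa = sorted(per)
                import numpy as np

                m = np.zeros((len(taxa), len(taxa)))
                for i in range(len(taxa)):
                    for j in range(i + 1, len(taxa)):
                        aln = global_align(per[taxa[i]], per[taxa[j]])
                        m[i, j] = m[j, i] = k2p_distance(aln).K
                tree = nj_tree(DistanceMatrix(taxa, m))
            tree_file.write_text(tree.to_newick() + "\n")
            outputs["tree.nwk"] = tree_file
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "blocks": asdict(cfg.blocks),
            "cns": asdict(cfg.cns),
            "ltr_rate": cfg.ltr_rate,
            "calibration": list(cfg.calibration),
            "bootstrap": cfg.bootstrap,
            "simulate": cfg.simulate,
            "lineages": list(cfg.lineages),
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
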
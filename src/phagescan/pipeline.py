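"""End-to-end annotation: compose the scanners into one report.

``annotate`` runs genome ingest -> ORF calling -> RBS scanning ->
embedded-ORF elimination -> terminator detection -> frameshift motif
search -> composition statistics, in that order, and returns an
:class:`AnnotationReport` that serializes losslessly to JSON.  The
shipped default configuration profile ("spp1-2018") carries the
annotation criteria used for the SPP1 genome.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import composition as comp
from . import motifs as motifs_mod
from . import orfcall, rbs, terminators
from .seqcore import Genome, Interval, as_rna, read_fasta, write_gff3

log = logging.getLogger("phagescan")

__all__ = ["AnnotationConfig", "AnnotationReport", "annotate", "export", "load_report"]


@dataclass
class AnnotationConfig:
    topology: str = "circular"
    min_aa: int = 45
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG")
    strand_mode: str = "heavy_only"
    coupling_max_gap: int = 1
    sd_model: rbs.SDModel = field(default_factory=rbs.SDModel)
    dual_start_codons: int = 15
    terminator_params: terminators.TerminatorParams = field(
        default_factory=terminators.TerminatorParams
    )
    at_island_window: int = 50
    at_island_threshold: float = 0.75
    min_ext: int = 10

    @classmethod
    def from_profile(cls, name_or_path: str = "spp1-2018") -> "AnnotationConfig":
        path = Path(name_or_path)
        if not path.exists():
            path_res = resources.files("phagescan") / "data" / f"{name_or_path}.yaml"
            with resources.as_file(path_res) as p:
                raw = yaml.safe_load(Path(p).read_text())
        else:
            raw = yaml.safe_load(path.read_text())
        orf = raw.get("orf", {})
        r = raw.get("rbs", {})
        t = raw.get("terminators", {})
        c = raw.get("composition", {})
        m = raw.get("motifs", {})
        return cls(
            topology=raw.get("topology", "circular"),
            min_aa=orf.get("min_aa", 45),
            start_codons=tuple(orf.get("start_codons", ["ATG", "GTG", "TTG"])),
            strand_mode=orf.get("strand_mode", "heavy_only"),
            coupling_max_gap=orf.get("coupling_max_gap", 1),
            sd_model=rbs.SDModel(
                antisd_as_printed=r.get("antisd", "UCUUUCCUCCACUAG"),
                anchor_index=r.get("anchor_index", 8),
                spacing_range=(r.get("spacing_min", 8), r.get("spacing_max", 14)),
                min_paired=r.get("min_paired", 4),
                max_mismatch=r.get("max_mismatch", 2),
                window=r.get("window", 25),
            ),
            dual_start_codons=r.get("dual_start_codons", 15),
            terminator_params=terminators.TerminatorParams(
                window=t.get("window", 60),
                min_stem=t.get("min_stem", 4),
                max_stem=t.get("max_stem", 15),
                loop_range=(t.get("loop_min", 3), t.get("loop_max", 12)),
                max_stem_mismatch=t.get("max_stem_mismatch", 1),
                min_u=t.get("min_u", 3),
                u_window=t.get("u_window", 8),
            ),
            at_island_window=c.get("at_island_window", 50),
            at_island_threshold=c.get("at_island_threshold", 0.75),
            min_ext=m.get("min_ext", 10),
        )


@dataclass
class AnnotationReport:
    genome_id: str
    genome_length: int
    topology: str
    stats: dict
    orfs: list[dict]
    coupling: list[dict]
    terminators: list[dict]
    slippery: list[dict]
    codon_usage: dict
    summary: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnnotationReport":
        return cls(**json.loads(text))


def _orf_record(orf, genome, config) -> dict:
    rec = {
        "id": orf.id,
        "start_nt": orf.start_nt,
        "stop_nt": orf.stop_nt,
        "strand": orf.strand,
        "start_codon": as_rna(orf.start_codon),
        "stop_codon": as_rna(orf.stop_codon),
        "length_aa": orf.length_aa,
        "wraps": orf.interval.wraps,
        "flags": sorted(orf.flags),
        "embedded_in": orf.embedded_in,
        "rbs": None,
        "dual_starts": [],
        "mass_kda": None,
    }
    seq = orfcall.orf_sequence(orf, genome)
    from .seqcore import translate

    protein, _ = translate(seq, initiator_met=True)
    rec["mass_kda"] = round(comp.protein_mass(protein) / 1000.0, 1)
    if orf.rbs is not None:
        rec["rbs"] = {
            "pattern": orf.rbs.pattern,
            "spacing": orf.rbs.spacing,
            "n_paired": orf.rbs.n_paired,
            "n_mismatch": orf.rbs.n_mismatch,
            "category": orf.rbs.category,
        }
    return rec


def annotate(genome_or_path, config: AnnotationConfig | None = None) -> AnnotationReport:
    """Run the full annotation pipeline on a genome (FASTA path or Genome)."""
    config = config or AnnotationConfig()
    if isinstance(genome_or_path, Genome):
        genome = genome_or_path
    else:
        genome = read_fasta(genome_or_path, topology=config.topology)
    log.info("genome %s: %d bp, %s", genome.id, genome.length, genome.topology)

    stats = comp.composition_report(
        genome, window=config.at_island_window, threshold=config.at_island_threshold
    )
    log.info("GC %.1f%%, forward-strand purines %.1f%%", stats.gc_pct, stats.purine_pct_fwd)

    orfs = orfcall.scan_orfs(
        genome,
        min_aa=config.min_aa,
        starts=config.start_codons,
        strand_mode=config.strand_mode,
    )
    log.info("ORF scan: %d candidates", len(orfs))

    rbs_results = {}
    for orf in orfs:
        match = rbs.scan_rbs(genome, orf.start_nt, orf.strand, model=config.sd_model)
        # only a canonical RBS protects an embedded ORF from elimination
        rbs_results[orf.id] = match if match and match.category == "canonical" else None
        orf.rbs = match
    orfs = orfcall.filter_embedded(orfs, rbs_results, genome)
    log.info("after embedded-ORF elimination: %d ORFs", len(orfs))

    coupling = [
        {"upstream": a, "downstream": b, "arrangement": arr}
        for a, b, arr in orfcall.detect_translational_coupling(
            orfs, genome, max_gap=config.coupling_max_gap
        )
    ]

    terms = terminators.find_terminators(genome, config.terminator_params)
    log.info("terminators: %d candidates", len(terms))

    slippery = []
    for orf in orfs:
        for site in motifs_mod.find_plus1_sites(orf, genome, min_ext=config.min_ext):
            slippery.append(dataclasses.asdict(site))
        for site in motifs_mod.find_minus1_sites(orf, genome, min_ext=config.min_ext):
            slippery.append(dataclasses.asdict(site))
    log.info("slippery sites: %d", len(slippery))

    usage = comp.codon_usage(orfcall.orf_sequence(o, genome) for o in orfs)

    orf_records = [_orf_record(o, genome, config) for o in orfs]
    for rec, orf in zip(orf_records, orfs):
        duals = rbs.detect_dual_starts(
            orf, genome, k=config.dual_start_codons, model=config.sd_model
        )
        rec["dual_starts"] = [
            {"offset_aa": d["offset_aa"], "start_nt": d["start_nt"], "pattern": d["rbs"].pattern}
            for d in duals
        ]

    summary: dict = {}
    if orf_records:
        frame = pd.DataFrame(
            [
                {
                    "start_nt": r["start_nt"],
                    "stop_nt": r["stop_nt"],
                    "start_codon": r["start_codon"],
                    "stop_codon": r["stop_codon"],
                    "length_aa": r["length_aa"],
                    "mm_kda": r["mass_kda"],
                }
                for r in orf_records
            ]
        )
        summary = comp.summarize_orf_table(frame, genome.length, genome.topology)

    return AnnotationReport(
        genome_id=genome.id,
        genome_length=genome.length,
        topology=genome.topology,
        stats={
            "gc_pct": stats.gc_pct,
            "purine_pct_fwd": stats.purine_pct_fwd,
            "purine_pct_rev": stats.purine_pct_rev,
            "heavy_strand": stats.heavy_strand,
            "at_islands": [
                {
                    "start": isl["interval"].start,
                    "end": isl["interval"].end,
                    "wraps": isl["interval"].wraps,
                    "at_fraction": isl["at_fraction"],
                }
                for isl in stats.at_islands
            ],
        },
        orfs=orf_records,
        coupling=coupling,
        terminators=[
            {
                "start_nt": t.interval.start,
                "end_nt": t.interval.end,
                "wraps": t.interval.wraps,
                "stem_len": t.stem_len,
                "loop_len": t.loop_len,
                "mismatches_in_stem": t.mismatches_in_stem,
                "u_tract_len": t.u_tract_len,
                "dG": round(t.dG, 2),
            }
            for t in terms
        ],
        slippery=slippery,
        codon_usage={
            "counts": usage.counts,
            "total_codons": usage.total_codons,
            "fractions": usage.fractions(),
        },
        summary=summary,
    )


def export(report: AnnotationReport, outdir: str | Path, genome: Genome | None = None, formats=("gff3", "tsv", "json")) -> list[Path]:
    """Write the report as GFF3 + Table-3-style TSV + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = outdir / "report.json"
        p.write_text(report.to_json())
        written.append(p)
    if "tsv" in formats:
        p = outdir / "orfs.tsv"
        rows = []
        for r in report.orfs:
            rbs_d = r["rbs"] or {}
            rows.append(
                {
                    "ORF": r["id"],
                    "RBS": rbs_d.get("pattern", ""),
                    "spacing": rbs_d.get("spacing", ""),
                    "start_codon": r["start_codon"],
                    "start_nt": r["start_nt"],
                    "stop_codon": r["stop_codon"],
                    "stop_nt": r["stop_nt"],
                    "length_aa": r["length_aa"],
                    "MM_kDa": r["mass_kda"],
                }
            )
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
        p2 = outdir / "terminators.tsv"
        pd.DataFrame(report.terminators).to_csv(p2, sep="\t", index=False)
        written.append(p2)
    if "gff3" in formats:
        if genome is None:
            genome = Genome(id=report.genome_id, seq="A" * report.genome_length, topology=report.topology)
        feats = []
        for r in report.orfs:
            iv = (
                Interval(r["start_nt"], r["stop_nt"], wraps=r["wraps"])
                if r["strand"] == "+"
                else Interval(r["stop_nt"], r["start_nt"], wraps=r["wraps"])
            )
            feats.append(
                {
                    "type": "CDS",
                    "interval": iv,
                    "strand": r["strand"],
                    "phase": 0,
                    "attributes": {"ID": r["id"]},
                }
            )
        for i, t in enumerate(report.terminators):
            feats.append(
                {
                    "type": "terminator",
                    "interval": Interval(t["start_nt"], t["end_nt"], wraps=t["wraps"]),
                    "strand": "+",
                    "score": t["dG"],
                    "attributes": {"ID": f"term_{i+1:03d}"},
                }
            )
        for i, s in enumerate(report.slippery):
            feats.append(
                {
                    "type": "recoding_signal",
                    "interval": Interval(s["position"], s["position"]),
                    "strand": "+",
                    "attributes": {"ID": f"slip_{i+1:02d}", "kind": s["kind"], "orf": s["orf_id"]},
                }
            )
        p = outdir / "features.gff3"
        write_gff3(genome, feats, p)
        written.append(p)
    return written


def load_report(path: str | Path) -> AnnotationReport:
    return AnnotationReport.from_json(Path(path).read_text())
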
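"""End-to-end orchestration: one config in, a report directory out.

Every stage writes a plain TSV (or Newick) artifact; the manifest records
input checksums, the config echo, and per-stage row counts.  Reruns with the
same config and seed produce byte-identical bundles.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import composition as comp
from . import gccontent as gc
from . import motifs as mot
from . import phylo
from . import segmentation as seg
from . import stretches as strt
from .seqio import read_alignment, read_fasta, join_metadata, pair_cds, read_tracks

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    proteins: str
    metadata: str
    alignment: str
    reference_id: str
    ref_core: tuple[int, int]
    out_dir: str
    cds: Optional[str] = None
    tracks: Optional[str] = None
    band_table: Optional[str] = None  # TSV: protein_id, band_label, band_gc
    stretch_mode: str = "strict"
    disorder_source: str = "proxy"  # proxy | tracks
    proximity_window: int = 5
    bootstrap: int = 100
    seed: Optional[int] = None
    k_cut: float = 70.0
    partial_fraction: float = 0.5
    aggregation: str = "sequence"  # trend aggregation: sequence | organism-mean
    repeat_min_unit: int = 10
    repeat_min_identity: float = 0.9
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["ref_core"] = tuple(raw["ref_core"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("proteins", "metadata", "alignment", "cds", "tracks", "band_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")
        if self.bootstrap > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when bootstrap replicates are requested")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report tables keyed by stage name.

    Any stage failure aborts with the stage name in the exception.  GC stages
    are skipped (with explicit markers in the manifest) when no CDS file is
    configured.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("armscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {}
    manifest: dict = {
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "inputs": {},
        "stages": {},
    }
    for name in ("proteins", "metadata", "alignment", "cds", "tracks", "band_table"):
        value = getattr(config, name)
        if value is not None:
            manifest["inputs"][name] = _sha256(value)

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    try:
        # ---- load -----------------------------------------------------
        name = stage("load")
        records = join_metadata(read_fasta(config.proteins, "protein"), config.metadata)
        if not records:
            raise PipelineError(name, "no records after metadata join")
        by_id = {r.id: r for r in records}
        families = {r.id: r.family for r in records}
        alignment = read_alignment(config.alignment)
        alignment.validate_against(records)
        pairs = []
        if config.cds is not None:
            cds = read_fasta(config.cds, "nucleotide")
            pairs = pair_cds(records, cds, validate=True)
        manifest["stages"][name] = {"records": len(records), "cds_pairs": len(pairs)}

        # ---- segmentation --------------------------------------------
        name = stage("segmentation")
        annotations_list = seg.project_core(
            alignment, config.reference_id, config.ref_core, config.partial_fraction
        )
        annotations_list = [a for a in annotations_list if a.protein_id in by_id]
        annotations = {a.protein_id: a for a in annotations_list}
        _write(seg.annotations_to_table(annotations_list), out / "regions.tsv")
        lengths_tbl = seg.region_lengths(annotations_list, families)
        _write(lengths_tbl, out / "region_lengths.tsv")
        report["regions"] = annotations
        report["region_lengths"] = lengths_tbl
        manifest["stages"][name] = {
            "segmented": sum(1 for a in annotations_list if a.status == "ok"),
            "partial": sum(1 for a in annotations_list if a.status == "partial"),
            "unsegmentable": sum(1 for a in annotations_list if a.status == "unsegmentable"),
        }

        # ---- composition + disorder ----------------------------------
        name = stage("composition")
        comp_tbl = comp.composition_table(records, annotations)
        _write(comp_tbl, out / "composition.tsv")
        report["composition"] = comp_tbl
        if config.disorder_source == "proxy":
            calls = [comp.disorder_proxy(r) for r in records]
        else:
            if config.tracks is None:
                raise PipelineError(name, "disorder_source=tracks but no tracks file")
            tracks = [t for t in read_tracks(config.tracks) if t.kind == "disorder"]
            by_pid: dict[str, list] = {}
            for t in tracks:
                by_pid.setdefault(t.protein_id, []).append(t)
            calls = [
                comp.consensus_disorder(ts) for ts in by_pid.values() if len(ts) >= 2
            ]
        dis_tbl = comp.disorder_table(calls, annotations, families)
        _write(dis_tbl, out / "disorder.tsv")
        report["disorder"] = dis_tbl
        manifest["stages"][name] = {"profiles": len(comp_tbl), "disorder_calls": len(calls)}

        # ---- stretches ------------------------------------------------
        name = stage("stretches")
        all_stretches = []
        for r in records:
            all_stretches.extend(strt.find_stretches(r, mode=config.stretch_mode))
        summary = strt.stretch_summary(all_stretches, annotations, families)
        _write(summary.attrs["detail"], out / "stretches.tsv")
        _write(summary, out / "stretch_summary.tsv")
        report["stretches"] = all_stretches
        report["stretch_summary"] = summary
        manifest["stages"][name] = {"stretches": len(all_stretches)}

        # ---- motifs + phospho proximity ------------------------------
        name = stage("motifs")
        all_hits = []
        for r in records:
            for pat in mot.BUILTIN_PATTERNS.values():
                all_hits.extend(mot.scan_pattern(r, pat))
        all_hits = mot.label_hits(all_hits, annotations)
        hits_tbl = pd.DataFrame(
            [dataclasses.asdict(h) for h in all_hits],
            columns=["protein_id", "pattern", "start", "end", "matched", "region"],
        )
        _write(hits_tbl, out / "motifs.tsv")
        presence = mot.motif_presence(all_hits, families)
        _write(presence, out / "motif_presence.tsv")
        sites = mot.sites_from_hits(
            [h for h in all_hits if h.pattern == "CK2"], by_id
        )
        if config.tracks is not None:
            for t in read_tracks(config.tracks):
                if t.kind == "phospho":
                    t.validate_against(by_id[t.protein_id])
                    sites.extend(
                        mot.PhosphoSite(t.protein_id, p,
                                        by_id[t.protein_id].residues[p - 1], "track")
                        for p in sorted(t.phospho)
                    )
        proximity = mot.phospho_proximity(sites, all_stretches, config.proximity_window)
        _write(proximity, out / "phospho_proximity.tsv")
        report["motifs"] = all_hits
        report["motif_presence"] = presence
        report["phospho_proximity"] = proximity
        manifest["stages"][name] = {"hits": len(all_hits), "phospho_sites": len(sites)}

        # ---- tandem repeats ------------------------------------------
        name = stage("repeats")
        repeats = []
        for r in records:
            repeats.extend(
                mot.find_tandem_repeats(
                    r, min_unit=config.repeat_min_unit,
                    min_identity=config.repeat_min_identity,
                )
            )
        rep_tbl = pd.DataFrame(
            {
                "protein_id": [x.protein_id for x in repeats],
                "start": [x.start for x in repeats],
                "unit_length": [x.unit_length for x in repeats],
                "copies": [x.copies for x in repeats],
                "min_identity": [x.min_identity for x in repeats],
            }
        )
        _write(rep_tbl, out / "repeats.tsv")
        report["repeats"] = repeats
        manifest["stages"][name] = {"repeats": len(repeats)}

        # ---- GC -------------------------------------------------------
        if pairs:
            name = stage("gc")
            gc_tbl = gc.gc_table(pairs, annotations)
            _write(gc_tbl, out / "gc.tsv")
            fits = gc.family_trends(gc_tbl, aggregation=config.aggregation)
            _write(gc.trends_table(fits), out / "trends.tsv")
            full_fits = [f for f in fits if f.part == "full"]
            if len(full_fits) >= 2:
                _write(gc.compare_slopes(full_fits), out / "slope_comparison.tsv")
            gene_cls = pd.DataFrame(
                {
                    "protein_id": gc_tbl["protein_id"],
                    "gc_full": gc_tbl["gc_full"],
                    "isochore": [
                        gc.classify_isochore(v).label for v in gc_tbl["gc_full"]
                    ],
                }
            )
            _write(gene_cls, out / "gene_isochore.tsv")
            if config.band_table is not None:
                bands = pd.read_csv(config.band_table, sep="\t")
                rows = []
                gc_by_id = dict(zip(gc_tbl["protein_id"], gc_tbl["gc_full"]))
                for _, b in bands.iterrows():
                    if b["protein_id"] not in gc_by_id:
                        continue
                    rec = gc.gene_vs_band(gc_by_id[b["protein_id"]], float(b["band_gc"]))
                    rows.append(
                        {
                            "protein_id": b["protein_id"],
                            "band_label": b.get("band_label", ""),
                            "gene_gc": rec.gene_gc, "band_gc": rec.band_gc,
                            "gene_class": rec.gene_class, "band_class": rec.band_class,
                            "concordant": rec.concordant,
                        }
                    )
                _write(pd.DataFrame(rows), out / "band_concordance.tsv")
            report["gc"] = gc_tbl
            report["trends"] = fits
            manifest["stages"][name] = {"genes": len(gc_tbl), "trend_fits": len(fits)}
        else:
            for marker in ("gc", "trends", "slope_comparison", "gene_isochore"):
                manifest["stages"][marker] = "skipped (no CDS configured)"

        # ---- phylogenies ---------------------------------------------
        name = stage("phylo")
        class_rows = []
        report["trees"] = {}
        for scope in ("full", "N", "C"):
            rows = [
                a.protein_id
                for a in annotations_list
                if a.status != "unsegmentable"
                and (scope == "full" or a.region_span(scope) is not None)
            ]
            if len(rows) < 3:
                manifest["stages"][f"tree_{scope}"] = "skipped (fewer than 3 rows)"
                continue
            tree = phylo.bootstrap_support(
                alignment, scope=scope, B=config.bootstrap,
                seed=(config.seed or 0) + {"full": 0, "N": 1, "C": 2}[scope],
                annotations=annotations, reference_id=config.reference_id,
                rows=rows,
            )
            (out / f"tree_{scope}.nwk").write_text(tree.to_newick() + "\n")
            partition = phylo.partition_classes(
                tree, {pid: families[pid] for pid in rows},
                k_cut=config.k_cut, scope=scope,
            )
            for fam in sorted(partition.classes):
                class_rows.append(
                    {
                        "scope": scope, "family": fam,
                        "class": partition.classes[fam],
                        "purity": partition.purity[fam],
                    }
                )
            report["trees"][scope] = tree
            report[f"classes_{scope}"] = partition
            manifest["stages"][f"tree_{scope}"] = {"leaves": len(rows)}
        _write(pd.DataFrame(class_rows), out / "classes.tsv")

        if config.figures:
            _render_figures(report, out)
    except PipelineError:
        raise
    except Exception as exc:  # attach the failing stage
        raise PipelineError(name, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["manifest"] = manifest
    return report


def _render_figures(report: dict, out: Path) -> None:
    """Optional bar-chart renderings of the report tables (not part of the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for key, value_col in (
        ("region_lengths", "mean"),
        ("composition", "pct_charged"),
        ("disorder", "pct_disordered"),
    ):
        tbl = report.get(key)
        if tbl is None or tbl.empty:
            continue
        df = tbl
        if key != "region_lengths":
            df = (
                tbl[tbl["region"].isin(["N", "core", "C"])]
                .groupby(["family", "region"], sort=True)[value_col]
                .mean()
                .reset_index()
            )
        fig, ax = plt.subplots(figsize=(8, 4))
        pivot = df.pivot(index="family", columns="region", values=value_col)
        pivot = pivot.reindex(columns=["N", "core", "C"])
        pivot.plot.bar(ax=ax, color=["red", "green", "blue"])
        ax.set_ylabel(value_col)
        fig.tight_layout()
        fig.savefig(out / f"fig_{key}.png", dpi=120)
        plt.close(fig)
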
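"""End-to-end pipeline driver.

Ties the stages together behind a single :class:`PipelineConfig`: read
labelled merged reads (or a pre-built OTU table), call OTUs, run the
curation cascade, and perform the community analysis, writing every
artifact plus a run manifest.  A single master seed reproduces a whole
run: stage seeds are derived from it deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import community, curation, fileio, otus

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """What to run, on which files, with which thresholds."""

    outdir: str = "bogforam_out"
    seed: int = 0
    # stage toggles
    call_otus: bool = False
    curate: bool = True
    analyze: bool = True
    # inputs
    reads_fasta: list[str] = field(default_factory=list)
    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    flagged_otus: str | None = None
    flagged_samples: str | None = None
    # stage parameters
    swarm_d: int = 1
    min_identity: float = 0.65
    curation: curation.CurationParams = field(default_factory=curation.CurationParams)
    unifrac_normalized: bool = True
    top_k: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cur = raw.pop("curation", {})
        cfg = cls(**raw)
        if cur:
            cfg.curation = curation.CurationParams(**cur)
        return cfg

    def fingerprint(self) -> str:
        """Digest of the scientific parameters (seed, thresholds, flags).

        Stage toggles and file paths are excluded so an artifact's header
        does not change when unrelated stages are switched on or off.
        """
        d = {
            "seed": self.seed,
            "swarm_d": self.swarm_d,
            "min_identity": self.min_identity,
            "curation": dataclasses.asdict(self.curation),
            "unifrac_normalized": self.unifrac_normalized,
            "top_k": self.top_k,
        }
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Returns the run manifest (also written to ``manifest.json``), listing
    the seed, parameters, input checksums and every output file.  Identical
    configs produce identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = {"seed": config.seed, "config_fingerprint": config.fingerprint()}
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "outputs": [],
    }

    def note_input(p: str | None):
        if p:
            manifest["inputs"][p] = _sha256(Path(p))

    def emit(name: str):
        manifest["outputs"].append(name)

    try:
        if config.call_otus:
            if not config.reads_fasta:
                raise ValueError("call_otus enabled but no reads_fasta given")
            for p in config.reads_fasta:
                note_input(p)
            reads = fileio.read_reads_fasta(config.reads_fasta)
            table, log = otus.call_otus(reads, d=config.swarm_d, min_identity=config.min_identity)
            fileio.write_otu_table(table, outdir / "otu_table_raw.tsv", header=head)
            log.to_csv(outdir / "otu_call_removed.tsv", sep="\t", index=False)
            emit("otu_table_raw.tsv")
            emit("otu_call_removed.tsv")
        elif config.table:
            note_input(config.table)
            table = fileio.read_otu_table(config.table)
        else:
            raise ValueError("need either call_otus with reads_fasta, or a table path")
    except Exception as exc:
        raise RuntimeError(f"stage 'call_otus' failed: {exc}") from exc

    if config.curate:
        try:
            flagged_otus = fileio.read_id_list(config.flagged_otus) if config.flagged_otus else []
            flagged_samples = fileio.read_id_list(config.flagged_samples) if config.flagged_samples else []
            note_input(config.flagged_otus)
            note_input(config.flagged_samples)
            table, report = curation.run_curation(
                table,
                flagged_otus=flagged_otus,
                flagged_samples=flagged_samples,
                params=config.curation,
                seed=stage_seed(config.seed, "rarefy"),
            )
            fileio.write_otu_table(table, outdir / "otu_table_curated.tsv", header=head)
            fileio.write_report(report, outdir / "curation_report.tsv", header=head)
            emit("otu_table_curated.tsv")
            emit("curation_report.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage 'curate' failed: {exc}") from exc

    if config.analyze:
        try:
            if not config.tree:
                raise ValueError("analyze enabled but no tree given")
            note_input(config.tree)
            tree = fileio.read_newick(config.tree)
            dm = community.weighted_unifrac(table, tree, normalized=config.unifrac_normalized)
            dm.to_dataframe().to_csv(outdir / "unifrac_distances.tsv", sep="\t")
            emit("unifrac_distances.tsv")
            ord_res = community.pcoa(dm)
            ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
            with open(outdir / "pcoa_eigen.tsv", "w") as fh:
                fh.write("axis\teigenvalue\tpercent_variance\n")
                npos = len(ord_res.percent_variance)
                for i, ev in enumerate(ord_res.eigenvalues):
                    pct = f"{ord_res.percent_variance[i]:.6f}" if i < npos else ""
                    fh.write(f"{i + 1}\t{ev:.10g}\t{pct}\n")
            emit("pcoa_coordinates.tsv")
            emit("pcoa_eigen.tsv")
            community.classify_table(table).to_csv(outdir / "abundance_classes.tsv", sep="\t", index=False)
            emit("abundance_classes.tsv")
            if config.metadata:
                note_input(config.metadata)
                metadata = fileio.read_metadata(config.metadata)
                summary, richness = community.occupancy_summary(table, metadata)
                summary.to_csv(outdir / "occupancy.tsv", sep="\t")
                richness.to_csv(outdir / "location_richness.tsv", sep="\t", header=True)
                emit("occupancy.tsv")
                emit("location_richness.tsv")
            k = min(config.top_k, len(table.otu_ids))
            if k >= 1 and table.total_reads() > 0:
                frac, ids = community.top_k_fraction(table, k)
                with open(outdir / "top_otus.tsv", "w") as fh:
                    fh.write(f"# seed={config.seed}\nk\tfraction\totu_ids\n{k}\t{frac:.6f}\t{','.join(ids)}\n")
                emit("top_otus.tsv")
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc

    manifest["output_checksums"] = {name: _sha256(outdir / name) for name in manifest["outputs"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
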
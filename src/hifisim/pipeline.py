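"""End-to-end orchestration: abundance -> in-silico PCR -> templates ->
subread simulation + consensus -> consolidated FASTQ with ground truth."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from hifisim import abundance as ab
from hifisim import passnum
from hifisim.amplicons import AmpliconSet, extract_amplicons
from hifisim.io_formats import (
    BarcodePair,
    RunConfig,
    SeqRecord,
    write_fasta,
    write_fastq,
    write_ground_truth,
)
from hifisim.readsim import ErrorModel, SimulatedRead, simulate_dataset
from hifisim.templates import assign_templates

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass
class RunManifest:
    """Counts, paths and timings of one completed run."""

    config: dict
    seed: int
    n_genomes: int = 0
    n_asvs: int = 0
    n_templates: int = 0
    n_zmws: int = 0
    n_reads: int = 0
    outputs: dict = dataclasses.field(default_factory=dict)
    stage_seconds: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if self.n_reads > self.n_zmws:
            raise ValueError("more reads than ZMWs")

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def run_pipeline(
    config: RunConfig,
    genomes: list[SeqRecord],
    barcodes: list[BarcodePair],
    out_dir: str | Path,
) -> tuple[RunManifest, list[SimulatedRead]]:
    """Execute the five-stage simulation and write all outputs.

    Output files: ``reads.fastq`` (Phred+33 CCS reads), ``truth.tsv``
    (read provenance), ``asvs.fasta`` (reference ASVs), ``counts.tsv``
    (ground-truth ASV x sample counts), ``manifest.json``.
    Fixed (config, seed) gives byte-identical outputs for any worker
    count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)
    manifest.config["error_ratio"] = list(manifest.config["error_ratio"])
    sample_ids = [bp.sample_id for bp in barcodes][: config.n_samples]
    if len(sample_ids) < config.n_samples:
        raise PipelineError(
            f"abundance: need {config.n_samples} barcode pairs, got {len(barcodes)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 17)))

    # stage 1: in-silico PCR (needed before abundance expansion)
    t0 = time.perf_counter()
    amplicon_sets: list[AmpliconSet] = []
    for g in genomes:
        aset = extract_amplicons(
            g,
            config.primer_fwd,
            config.primer_rev,
            max_mismatch=config.max_primer_mismatch,
            min_len=config.min_product_len,
            max_len=config.max_product_len,
        )
        amplicon_sets.append(aset)
        logger.info("genome %s: %d amplicons, %d ASVs", g.id, aset.n_amplicons, len(aset.asv_seqs))
    if all(a.n_amplicons == 0 for a in amplicon_sets):
        raise PipelineError("amplicons: no extractable amplicons in any genome")
    manifest.stage_seconds["amplicons"] = time.perf_counter() - t0

    # stage 2: abundance simulation, genome molarity -> ASV counts
    t0 = time.perf_counter()
    try:
        molarity = ab.sample_genome_molarity(
            config.abundance_dist, config.abundance_params, len(genomes), rng
        )
        asv_ids, asv_intensity = ab.expand_to_asv(
            molarity, amplicon_sets, [g.id for g in genomes]
        )
        model = ab.VariabilityModel()
        counts = ab.simulate_count_table(
            asv_ids, asv_intensity, sample_ids, config.reads_per_sample, model, rng
        )
    except Exception as exc:  # pragma: no cover - stage attribution
        raise PipelineError(f"abundance: {exc}") from exc
    manifest.stage_seconds["abundance"] = time.perf_counter() - t0

    # stage 3: barcoded template construction
    t0 = time.perf_counter()
    templates = assign_templates(
        counts,
        amplicon_sets,
        barcodes,
        config.primer_fwd,
        config.primer_rev,
        rng=np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 19))),
    )
    manifest.stage_seconds["templates"] = time.perf_counter() - t0

    # stage 4: subread simulation + consensus
    t0 = time.perf_counter()
    np_dist = passnum.from_config(
        config.np_source,
        config.np_min,
        config.np_max,
        mu=config.np_mu,
        sigma=config.np_sigma,
        np_table=config.np_table,
    )
    error_model = ErrorModel(
        accuracy=config.subread_accuracy, ratio=config.error_ratio
    )
    reads = simulate_dataset(
        templates, np_dist, error_model, seed=config.seed, workers=config.workers
    )
    manifest.stage_seconds["readsim"] = time.perf_counter() - t0

    # stage 5: consolidation
    t0 = time.perf_counter()
    fastq = out_dir / "reads.fastq"
    truth = out_dir / "truth.tsv"
    asv_fa = out_dir / "asvs.fasta"
    counts_tsv = out_dir / "counts.tsv"
    n_written = write_fastq(reads, fastq)
    write_ground_truth(reads, truth)
    asv_records = [
        SeqRecord(id=asv_id, seq=seq)
        for aset in amplicon_sets
        for asv_id, seq in aset.asv_seqs.items()
    ]
    write_fasta(asv_records, asv_fa)
    with open(counts_tsv, "w") as fh:
        fh.write("asv_id\t" + "\t".join(counts.sample_ids) + "\n")
        for i, asv_id in enumerate(counts.asv_ids):
            fh.write(asv_id + "\t" + "\t".join(map(str, counts.counts[i])) + "\n")
    manifest.stage_seconds["consolidate"] = time.perf_counter() - t0

    manifest.n_genomes = len(genomes)
    manifest.n_asvs = len(asv_records)
    manifest.n_templates = len(templates)
    manifest.n_zmws = sum(c for _, c in templates)
    manifest.n_reads = n_written
    manifest.outputs = {
        "fastq": str(fastq),
        "truth": str(truth),
        "asvs": str(asv_fa),
        "counts": str(counts_tsv),
    }
    manifest.validate()
    manifest.to_file(out_dir / "manifest.json")
    return manifest, reads
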
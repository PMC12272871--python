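"""Pipeline assembly: run both terminal analyses and write the report bundle.

Read counts at every filter (reads in, 5'-anchored, tag+adaptor-anchored)
are logged and written out: the counts are the audit trail for what each
extraction step discarded, and every table carries its normalization
denominator explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

from .core import Read, TemplateSpec, read_fastq
from .five_prime import (
    classify_five_prime,
    extract_five_prime,
    five_prime_table,
    summarize_five_prime,
)
from .three_prime import (
    classify_three_prime,
    compute_fidelity_report,
    extract_three_prime,
    size_distribution,
    top_sequences_at_size,
)

log = logging.getLogger("termini")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    reads: Path
    template: Path | TemplateSpec
    enzyme: str = ""
    expected_size: Optional[int] = None
    top_n_five: int = 10
    top_n_three: int = 5
    search_span: int = 10
    max_mismatches: int = 0
    revcomp_reads: bool = False  # reverse-complement on ingest (library orientation)
    outdir: Path = Path("termini_out")

    def load_template(self) -> TemplateSpec:
        if isinstance(self.template, TemplateSpec):
            return self.template
        if not Path(self.template).exists():
            raise PipelineError("config", f"template file not found: {self.template}")
        return TemplateSpec.from_yaml(self.template)


def run_pipeline(cfg: RunConfig, reads: Optional[List[Read]] = None) -> dict:
    """Execute extraction -> tables -> classification -> fidelity; write files.

    ``reads`` may be supplied in memory; otherwise ``cfg.reads`` is
    parsed as FASTQ. Returns the report bundle as a dict (also written
    as TSV/JSON files under ``cfg.outdir``).
    """
    template = cfg.load_template()
    expected = cfg.expected_size or template.tag_end_offset
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if reads is None:
        try:
            reads = list(read_fastq(cfg.reads))
        except Exception as exc:  # noqa: BLE001 - wrapped with stage name
            raise PipelineError("input", f"cannot read {cfg.reads}: {exc}") from exc
    if cfg.revcomp_reads:
        from .core import revcomp

        reads = [Read(r.id, revcomp(r.seq), r.qual[::-1] if r.qual else None) for r in reads]
    n_in = len(reads)
    if n_in == 0:
        raise PipelineError("extraction", "no reads in input")
    log.info("reads in: %d", n_in)

    # --- 5' stage
    five_records = [
        r
        for r in (extract_five_prime(rd, max_mismatches=cfg.max_mismatches) for rd in reads)
        if r
    ]
    n5 = len(five_records)
    log.info("5' adaptor-anchored: %d (skipped %d)", n5, n_in - n5)
    if n5 == 0:
        raise PipelineError("five_prime", "no read matched the 5' anchor")
    table5 = five_prime_table(five_records)
    summary5 = summarize_five_prime(five_records, template, cfg.search_span)
    df5 = table5.to_frame()
    df5["label"] = [
        classify_five_prime(s, template, cfg.search_span).category
        for s in df5["sequence"]
    ]
    df5.head(cfg.top_n_five).to_csv(
        outdir / "five_prime_table.tsv", sep="\t", index=False
    )
    with open(outdir / "five_prime_summary.json", "w") as fh:
        json.dump(summary5, fh, indent=2)

    # --- 3' stage
    three_records = [
        r
        for r in (extract_three_prime(rd, max_mismatches=cfg.max_mismatches) for rd in reads)
        if r
    ]
    n3 = len(three_records)
    log.info("tag+adaptor-anchored: %d (skipped %d)", n3, n_in - n3)
    if n3 == 0:
        raise PipelineError("three_prime", "no read matched tag and 3' adaptor")
    dist = size_distribution(three_records)
    dist.to_frame().to_csv(outdir / "size_distribution.tsv", sep="\t", index=False)
    top3 = top_sequences_at_size(three_records, expected, cfg.top_n_three)
    dft = top3.to_frame()
    dft["label"] = [
        classify_three_prime(s, template).category for s in dft["sequence"]
    ]
    dft.to_csv(outdir / f"top_at_size_{expected}.tsv", sep="\t", index=False)
    labels = [
        (r.read_id, r.size, *_label_fields(r.segment, template))
        for r in three_records
    ]
    import pandas as pd

    pd.DataFrame(
        labels, columns=["read_id", "size", "category", "extension"]
    ).to_csv(outdir / "three_prime_labels.tsv", sep="\t", index=False)
    fidelity = compute_fidelity_report(
        three_records, template, enzyme=cfg.enzyme, n_reads_in=n_in,
        expected_size=expected,
    )
    with open(outdir / "fidelity_report.json", "w") as fh:
        json.dump(fidelity.to_dict(), fh, indent=2)

    counts = {
        "reads_in": n_in,
        "five_prime_extracted": n5,
        "five_prime_skipped": n_in - n5,
        "three_prime_extracted": n3,
        "three_prime_skipped": n_in - n3,
    }
    with open(outdir / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)

    return {
        "counts": counts,
        "five_prime_summary": summary5,
        "five_prime_table": table5,
        "size_distribution": dist,
        "top_at_expected_size": top3,
        "fidelity": fidelity,
    }


def _label_fields(segment: str, template: TemplateSpec):
    lab = classify_three_prime(segment, template)
    return lab.category, lab.extension
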
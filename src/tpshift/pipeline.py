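"""End-user pipeline: FASTA in, frameshift calls and peptides out."""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

from .calibrate import GapPenaltyTable, default_gap_table
from .ga import GAConfig
from .sequence import CodingSequence, sanitize
from .significance import RESULT_COLUMNS, SignificanceConfig, analyze_sequence

logger = logging.getLogger("tpshift")

__all__ = ["RunConfig", "run_fasta", "split_and_translate", "write_peptides_fasta"]

#: subsequences at most this long are not translated
MIN_SUBSEQ_NT = 60
#: peptides at most this long are not emitted
MIN_PEPTIDE_AA = 20


@dataclass(frozen=True)
class RunConfig:
    input_fasta: str
    output_tsv: str
    ga: GAConfig = field(default_factory=GAConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    gap_table_path: str | None = None
    min_subseq_nt: int = MIN_SUBSEQ_NT
    min_peptide_aa: int = MIN_PEPTIDE_AA
    seed: int = 0
    resume: bool = True

    def __post_init__(self):
        if self.min_subseq_nt <= 0 or self.min_peptide_aa <= 0:
            raise ValueError("translation thresholds must be positive")


def write_sanitization_log(path, entries, append=False) -> None:
    """TSV log of symbol replacements: id, position, original, replacement."""
    new_file = not (append and os.path.exists(path))
    with open(path, "a" if not new_file else "w") as fh:
        if new_file:
            fh.write("id\tposition\toriginal\treplacement\n")
        for rid, pos, orig, sub in entries:
            fh.write(f"{rid}\t{pos}\t{orig}\t{sub}\n")


def _done_ids(path):
    if not os.path.exists(path):
        return set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row["id"] for row in reader}


def run_fasta(config: RunConfig):
    """Analyse every record of a FASTA file; append rows to the output TSV.

    Fully seeded (per-record seeds derive from ``config.seed`` and the
    record index) and resumable: ids already present in the output are
    skipped.  Per-record failures are logged and the run continues.
    """
    records = list(SeqIO.parse(config.input_fasta, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {config.input_fasta!r}")
    table = (
        GapPenaltyTable.from_yaml(config.gap_table_path)
        if config.gap_table_path
        else default_gap_table()
    )
    done = _done_ids(config.output_tsv) if config.resume else set()
    new_file = not (config.resume and os.path.exists(config.output_tsv))
    results = []
    mode = "w" if new_file else "a"
    with open(config.output_tsv, mode, newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS, delimiter="\t")
        if new_file:
            writer.writeheader()
        for idx, rec in enumerate(records):
            if rec.id in done:
                logger.info("skipping %s (already in output)", rec.id)
                continue
            base_seed = (config.seed * 1_000_003 + idx) % (2**31 - 1)
            try:
                seq, repl = sanitize(str(rec.seq), seed=base_seed, id=rec.id)
                if repl:
                    logger.info("%s: sanitized %d symbols", rec.id, len(repl))
                    write_sanitization_log(
                        config.output_tsv + ".sanitized.tsv",
                        [(rec.id, pos, orig, sub) for pos, orig, sub in repl],
                        append=True,
                    )
                ga_cfg = replace(config.ga, seed=base_seed + 1)
                sig_cfg = replace(config.significance, seed=base_seed + 2)
                res = analyze_sequence(seq, ga_cfg, sig_cfg, gap_table=table)
            except Exception:
                logger.exception("analysis failed for %s; continuing", rec.id)
                continue
            writer.writerow(res.to_row())
            fh.flush()
            results.append(res)
            logger.info(
                "%s: N=%d X=%.2f calls=%d", rec.id, res.N, res.X, len(res.calls)
            )
    return results


def split_and_translate(
    seq: CodingSequence,
    calls,
    min_subseq_nt: int = MIN_SUBSEQ_NT,
    min_peptide_aa: int = MIN_PEPTIDE_AA,
):
    """Split at call coordinates and translate the two alternative frames.

    Subsequence boundaries are the call positions (sorted); each
    subsequence longer than ``min_subseq_nt`` is translated with the
    standard genetic code in frame offsets +1 and +2 relative to the frame
    in which the subsequence begins (the annotated frame is the one the
    gene already encodes).  Stops render as '*' and do not truncate the
    peptide; peptides longer than ``min_peptide_aa`` are returned as
    ``(header, peptide)`` tuples.
    """
    positions = sorted({c.position for c in calls})
    if not positions:
        return []
    bounds = [0] + positions + [seq.N]
    bases = seq.bases
    out = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        sub = bases[start:end]
        if len(sub) <= min_subseq_nt:
            continue
        for offset in (1, 2):
            frame_nt = sub[offset:]
            frame_nt = frame_nt[: len(frame_nt) - len(frame_nt) % 3]
            if not frame_nt:
                continue
            pep = str(Seq(frame_nt).translate(to_stop=False))
            if len(pep) > min_peptide_aa:
                header = f"{seq.id}|{start + 1}-{end}|frame+{offset}"
                out.append((header, pep))
    return out


def write_peptides_fasta(path, peptides) -> None:
    with open(path, "w") as fh:
        for header, pep in peptides:
            fh.write(f">{header}\n")
            for k in range(0, len(pep), 60):
                fh.write(pep[k : k + 60] + "\n")
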
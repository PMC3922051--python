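"""Demultiplexing, quality filtering and the false-amplicon probe screen.

Reads are first assigned to samples by their 8-nt barcode prefix, then
filtered with the pyrosequencing criteria (mean quality < 25, any 50-bp
window of mean quality < 25, >=1 ambiguous base, length < 150 nt,
homopolymer runs > 6 bp), and finally screened for off-target PCR products:
a genuine 18S read must start with the complete forward primer 1A and carry
at least one of the internal probes Euk381/Euk422 somewhere downstream
within 2 mismatches.  Reads failing the screen are false-positive
amplification of non-rRNA genes and are discarded.

Each read receives exactly one rejection reason — the first failing rule in
a fixed order — so the per-sample report is reproducible and conservative:
input = qualified + sum(rejected-by-reason).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from brine18s.constants import (
    FORWARD_PRIMER_1A,
    PROBE_EUK381,
    PROBE_EUK422,
    REVERSE_PRIMER_564R,
)
from brine18s.io import Read

# rejection reasons, in the order they are tested
BARCODE = "BARCODE"
LOWQ_MEAN = "LOWQ_MEAN"
LOWQ_WINDOW = "LOWQ_WINDOW"
AMBIG = "AMBIG"
SHORT = "SHORT"
HOMOPOLYMER = "HOMOPOLYMER"
NO_PRIMER = "NO_PRIMER"
NO_PROBE = "NO_PROBE"

REASONS = (BARCODE, LOWQ_MEAN, LOWQ_WINDOW, AMBIG, SHORT, HOMOPOLYMER, NO_PRIMER, NO_PROBE)

UNASSIGNED = "unassigned"


@dataclasses.dataclass
class QCParams:
    min_mean_quality: float = 25.0
    quality_window: int = 50
    max_ambiguous: int = 0
    min_length: int = 150
    max_homopolymer: int = 6
    barcode_mismatches: int = 0
    probe_max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        for name in ("quality_window", "max_ambiguous", "max_homopolymer",
                     "barcode_mismatches", "probe_max_mismatches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclasses.dataclass
class ProbeSet:
    forward_primer: str = FORWARD_PRIMER_1A
    reverse_primer: str = REVERSE_PRIMER_564R
    probes: tuple[str, ...] = (PROBE_EUK381, PROBE_EUK422)

    def __post_init__(self) -> None:
        for seq in (self.forward_primer, self.reverse_primer, *self.probes):
            if set(seq) - set("ACGT"):
                raise ValueError(f"probe/primer sequences must be uppercase ACGT: {seq!r}")


def find_approx_match(sequence: str, pattern: str, max_mismatches: int) -> list[int]:
    """All 0-based offsets where ``pattern`` matches within Hamming distance.

    No indels are considered; an ambiguous base in the sequence counts as a
    mismatch.  A pattern longer than the sequence yields no matches.
    """
    n, m = len(sequence), len(pattern)
    if m > n or m == 0:
        return []
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    mismatches = (windows != pat).sum(axis=1)
    return np.flatnonzero(mismatches <= max_mismatches).tolist()


def demultiplex(
    reads: list[Read],
    mapping: dict[str, str],
    barcode_mismatches: int = 0,
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Partition reads by barcode prefix; trims the barcode on assignment.

    A read goes to the unique sample whose barcode matches its prefix within
    the allowed mismatches; ambiguous or non-matching prefixes are returned
    in the unassigned set.
    """
    barcodes = list(mapping.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("mapping contains duplicate barcodes")
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("barcodes must all have the same length")
    blen = len(barcodes[0])
    per_sample: dict[str, list[Read]] = {s: [] for s in mapping}
    unassigned: list[Read] = []
    for read in reads:
        prefix = read.seq[:blen]
        hits = [
            sample
            for sample, bc in mapping.items()
            if len(prefix) == blen
            and sum(a != b for a, b in zip(prefix, bc)) <= barcode_mismatches
        ]
        if len(hits) == 1:
            trimmed = read.trim_prefix(blen)
            trimmed.sample_id = hits[0]
            per_sample[hits[0]].append(trimmed)
        else:
            unassigned.append(read)
    return per_sample, unassigned


def quality_filter(read: Read, params: QCParams) -> tuple[str, str | None]:
    """Return ("PASS", None) or ("FAIL", reason) — first failing rule wins."""
    if len(read.seq) == 0:
        return "FAIL", SHORT
    qual = np.asarray(read.qual, dtype=float)
    if qual.mean() < params.min_mean_quality:
        return "FAIL", LOWQ_MEAN
    w = params.quality_window
    if 0 < w <= len(qual):
        csum = np.concatenate([[0.0], np.cumsum(qual)])
        window_means = (csum[w:] - csum[:-w]) / w
        if (window_means < params.min_mean_quality).any():
            return "FAIL", LOWQ_WINDOW
    n_ambig = sum(1 for c in read.seq if c not in "ACGT")
    if n_ambig > params.max_ambiguous:
        return "FAIL", AMBIG
    if len(read.seq) < params.min_length:
        return "FAIL", SHORT
    run = 1
    longest = 1
    for a, b in zip(read.seq, read.seq[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    if longest > params.max_homopolymer:
        return "FAIL", HOMOPOLYMER
    return "PASS", None


def probe_screen(
    read: Read, probeset: ProbeSet | None = None, params: QCParams | None = None
) -> tuple[str, str | None, Read | None]:
    """Screen a demultiplexed read for primer and internal probes.

    Returns ``("KEEP", None, insert)`` with the primer trimmed from the
    retained insert, or ``("DROP", reason, None)`` where reason is
    NO_PRIMER (complete forward primer absent at the read start, exact
    match) or NO_PROBE (neither probe occurs downstream of the primer
    within the allowed mismatches).
    """
    probeset = probeset or ProbeSet()
    params = params or QCParams()
    primer = probeset.forward_primer
    if not read.seq.startswith(primer):
        return "DROP", NO_PRIMER, None
    insert = read.trim_prefix(len(primer))
    for probe in probeset.probes:
        if find_approx_match(insert.seq, probe, params.probe_max_mismatches):
            return "KEEP", None, insert
    return "DROP", NO_PROBE, None


def run_qc(
    reads: list[Read],
    mapping: dict[str, str],
    probeset: ProbeSet | None = None,
    params: QCParams | None = None,
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Demultiplex + quality filter + probe screen.

    Returns per-sample qualified inserts (barcode and primer trimmed) and a
    QC report with one row per sample (plus ``unassigned``) and columns
    ``input``, one per rejection reason, and ``qualified``.
    """
    probeset = probeset or ProbeSet()
    params = params or QCParams()
    per_sample, unassigned = demultiplex(reads, mapping, params.barcode_mismatches)
    rows = {s: {"input": 0, **{r: 0 for r in REASONS}, "qualified": 0} for s in mapping}
    rows[UNASSIGNED] = {"input": len(unassigned), **{r: 0 for r in REASONS}, "qualified": 0}
    rows[UNASSIGNED][BARCODE] = len(unassigned)
    qualified: dict[str, list[Read]] = {s: [] for s in mapping}
    for sample, sample_reads in per_sample.items():
        rows[sample]["input"] = len(sample_reads)
        for read in sample_reads:
            status, reason = quality_filter(read, params)
            if status == "FAIL":
                rows[sample][reason] += 1
                continue
            verdict, reason, insert = probe_screen(read, probeset, params)
            if verdict == "DROP":
                rows[sample][reason] += 1
                continue
            qualified[sample].append(insert)
            rows[sample]["qualified"] += 1
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "sample"
    return qualified, report
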
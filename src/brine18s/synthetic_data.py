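"""Synthetic 454-style 18S amplicon reads with full ground truth.

The generator emulates the structure of a multiplexed pyrosequencing run of
barcoded 18S V1-V3 amplicons: a kingdom-labelled reference panel is evolved
from per-kingdom root sequences, reads are drawn from per-sample taxon
mixtures as ``barcode + forward primer + template-derived insert`` with
substitution and homopolymer-indel errors and decaying per-base qualities,
and configurable fractions of reads are planted with exactly one QC
violation each (false non-rRNA amplicon, short read, ambiguous base,
over-long homopolymer, low-quality stretch, corrupt barcode).  Every read
gets a ground-truth record so quality control, clustering and placement can
be scored exactly.

Two deliberate idealisations keep the ground truth unambiguous: the primer
and both internal probe sites are conserved — sequencing errors never fall
inside them — and false amplicons are rejection-sampled to sit at >=3
mismatches from both probes at every offset.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from brine18s import io as b18io
from brine18s.constants import (
    DNA_ALPHABET,
    FORWARD_PRIMER_1A,
    PROBE_EUK381,
    PROBE_EUK422,
    SAMPLE_BARCODES,
)

BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)

# planted-violation labels (at most one per read)
NO_PROBE = "NO_PROBE"
SHORT = "SHORT"
AMBIG = "AMBIG"
HOMOPOLYMER = "HOMOPOLYMER"
LOWQ = "LOWQ"
BAD_BARCODE = "BAD_BARCODE"

VIOLATION_ORDER = (NO_PROBE, SHORT, AMBIG, HOMOPOLYMER, LOWQ, BAD_BARCODE)


def probe_layout(seq_length: int) -> dict[str, tuple[int, int]]:
    """Fixed conserved windows (0-based, half-open) for a template length.

    The forward primer occupies the template start; the two internal probes
    sit downstream, mirroring their position between the 1A and 564R sites.
    """
    if seq_length < 200:
        raise ValueError("template length must be >= 200")
    e381 = min(180, seq_length - 80)
    e422 = e381 + 41
    return {
        "primer": (0, len(FORWARD_PRIMER_1A)),
        "euk381": (e381, e381 + len(PROBE_EUK381)),
        "euk422": (e422, e422 + len(PROBE_EUK422)),
    }


@dataclasses.dataclass
class ReferencePanel:
    """Kingdom-labelled 18S-like reference sequences.

    entries: list of ``(id, kingdom_label, sequence)``; all sequences share
    one length and carry the primer/probe sites verbatim at the layout
    offsets.
    """

    entries: list[tuple[str, str, str]]
    seq_length: int

    def __post_init__(self) -> None:
        for _, _, seq in self.entries:
            if set(seq) - set(DNA_ALPHABET):
                raise ValueError("panel sequences must be unambiguous ACGT")

    @property
    def kingdoms(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, k, _ in self.entries:
            seen.setdefault(k)
        return list(seen)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def sequence(self, entry_id: str) -> str:
        for eid, _, seq in self.entries:
            if eid == entry_id:
                return seq
        raise KeyError(entry_id)

    def layout(self) -> dict[str, tuple[int, int]]:
        return probe_layout(self.seq_length)

    def to_fasta(self, path: str | Path) -> Path:
        return b18io.write_fasta(
            ((f"{eid}|{kingdom}", seq) for eid, kingdom, seq in self.entries), path
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        entries = []
        length = None
        for name, seq in b18io.read_fasta(path):
            eid, _, kingdom = name.partition("|")
            if not kingdom:
                raise ValueError(f"reference header {name!r} lacks '|kingdom' suffix")
            entries.append((eid, kingdom, seq))
            length = len(seq) if length is None else length
        if not entries:
            raise ValueError(f"empty reference panel: {path}")
        return cls(entries, length)


@dataclasses.dataclass
class ErrorModel:
    """454-style error and quality model.

    substitution_rate: per-base substitution probability (conserved primer
    and probe windows are exempt).
    homopolymer_indel_rate: per-run probability of a +/-1 indel at
    homopolymer runs of >=3 nt, the dominant pyrosequencing error mode.
    q_start/q_end: Phred quality decays linearly from q_start at the first
    base to q_end at the last; q_jitter adds uniform integer noise.
    """

    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01
    q_start: int = 38
    q_end: int = 28
    q_jitter: int = 2


@dataclasses.dataclass
class SimulationConfig:
    samples: list[tuple[str, str]]  # (sample_id, 8-nt barcode)
    n_reads: int = 200
    composition: dict[str, dict[str, float]] | None = None  # sample -> template -> weight
    error: ErrorModel = dataclasses.field(default_factory=ErrorModel)
    false_amplicon_fraction: float = 0.0
    short_read_fraction: float = 0.0
    ambiguous_base_fraction: float = 0.0
    homopolymer_fraction: float = 0.0
    lowq_fraction: float = 0.0
    bad_barcode_fraction: float = 0.0
    reverse_complement_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        barcodes = [b for _, b in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcode collision: sample barcodes must be unique")
        for sid, b in self.samples:
            if len(b) != 8 or set(b) - set(DNA_ALPHABET):
                raise ValueError(f"sample {sid}: barcode must be 8 nt over ACGT, got {b!r}")
        fracs = self._fractions()
        if any(f < 0 or f > 1 for f in fracs.values()):
            raise ValueError("violation fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1 + 1e-9:
            raise ValueError("violation fractions sum to more than 1")
        if self.composition is not None:
            for sid, weights in self.composition.items():
                total = sum(weights.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(f"sample {sid}: mixture weights sum to {total}, not 1")

    def _fractions(self) -> dict[str, float]:
        return {
            NO_PROBE: self.false_amplicon_fraction,
            SHORT: self.short_read_fraction,
            AMBIG: self.ambiguous_base_fraction,
            HOMOPOLYMER: self.homopolymer_fraction,
            LOWQ: self.lowq_fraction,
            BAD_BARCODE: self.bad_barcode_fraction,
        }

    def mapping(self) -> dict[str, str]:
        return dict(self.samples)


def default_config(**kwargs) -> SimulationConfig:
    """A seven-sample configuration using the study's barcodes."""
    kwargs.setdefault("samples", list(SAMPLE_BARCODES.items()))
    return SimulationConfig(**kwargs)


ARCHETYPE_OF_SAMPLE = {
    "Mat": "mat-like",
    "NDW": "sediment-like",
    "DBI": "interface-like",
    "DS3": "sediment-like",
    "DS6": "sediment-like",
    "BS8": "sediment-like",
    "BS9": "sediment-like",
}


def archetype_compositions(
    panel: ReferencePanel,
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Three community archetypes over the default seven samples.

    Emulates the habitat structure of the study design: a diverse
    microbial-mat community (uniform over the panel), a brine-seawater
    interface community dominated by one lineage, and fungus-dominated
    sediment/bottom-water communities.  Returns (per-sample mixture
    weights, per-sample archetype labels).
    """
    sample_ids = list(sample_ids) if sample_ids is not None else list(ARCHETYPE_OF_SAMPLE)
    kingdoms = panel.kingdoms
    if len(kingdoms) < 4:
        raise ValueError("archetype design needs a panel with >= 4 kingdoms")
    by_kingdom: dict[str, list[str]] = {}
    for eid, kingdom, _ in panel.entries:
        by_kingdom.setdefault(kingdom, []).append(eid)

    def spread(weight_per_kingdom: dict[str, float]) -> dict[str, float]:
        weights: dict[str, float] = {}
        for kingdom, w in weight_per_kingdom.items():
            members = by_kingdom[kingdom]
            for eid in members:
                weights[eid] = w / len(members)
        total = sum(weights.values())
        return {eid: w / total for eid, w in weights.items()}

    uniform = 1.0 / len(kingdoms)
    archetype_weights = {
        "mat-like": spread({k: uniform for k in kingdoms}),
        "sediment-like": spread({kingdoms[0]: 0.85, kingdoms[1]: 0.15}),
        "interface-like": spread({kingdoms[2]: 0.75, kingdoms[3]: 0.25}),
    }
    groups = {s: ARCHETYPE_OF_SAMPLE.get(s, "sediment-like") for s in sample_ids}
    composition = {s: archetype_weights[groups[s]] for s in sample_ids}
    return composition, groups


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    rate: float,
    mutable: np.ndarray,
) -> np.ndarray:
    """Substitute bases at ``rate`` on the positions flagged mutable."""
    out = seq.copy()
    hits = np.flatnonzero(mutable & (rng.random(seq.size) < rate))
    for i in hits:
        choices = BASES[BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _break_long_runs(
    rng: np.random.Generator, seq: np.ndarray, mutable: np.ndarray, max_run: int = 6
) -> None:
    """Substitute the middle of homopolymer runs longer than ``max_run``.

    Templates must satisfy the homopolymer QC rule themselves, otherwise
    reads copied from them could never pass the filter.
    """
    while True:
        s = seq.tobytes().decode()
        pos = 0
        broke = False
        for base, group in itertools.groupby(s):
            run = len(list(group))
            if run > max_run:
                mid_candidates = [
                    p for p in range(pos, pos + run) if mutable[p]
                ] or [pos + run // 2]
                mid = mid_candidates[len(mid_candidates) // 2]
                choices = BASES[BASES != seq[mid]]
                seq[mid] = choices[rng.integers(0, 3)]
                broke = True
            pos += run
        if not broke:
            return


def _plant_motifs(seq: np.ndarray, layout: dict[str, tuple[int, int]]) -> None:
    for motif, (start, _) in zip(
        (FORWARD_PRIMER_1A, PROBE_EUK381, PROBE_EUK422),
        (layout["primer"], layout["euk381"], layout["euk422"]),
    ):
        seq[start : start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _mutable_mask(length: int, layout: dict[str, tuple[int, int]]) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for start, end in layout.values():
        mask[start:end] = False
    return mask


def generate_reference_panel(
    n_kingdoms: int = 23,
    per_kingdom: int = 5,
    seq_length: int = 600,
    inter_kingdom_divergence: float = 0.30,
    intra_kingdom_divergence: float = 0.03,
    seed: int = 0,
) -> ReferencePanel:
    """Evolve a panel of ``n_kingdoms x per_kingdom`` reference sequences.

    One root per kingdom is mutated from a common ancestor so that roots of
    different kingdoms differ by about ``inter_kingdom_divergence``; the
    members within a kingdom differ from their root by about
    ``intra_kingdom_divergence``.  Primer and probe sites are conserved in
    every sequence, giving the probe screen a guaranteed positive control.
    """
    if not (0 < intra_kingdom_divergence < inter_kingdom_divergence < 0.75):
        raise ValueError("need 0 < intra < inter < 0.75 divergence")
    layout = probe_layout(seq_length)
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, seq_length)
    _plant_motifs(ancestor, layout)
    mutable = _mutable_mask(seq_length, layout)
    entries = []
    for k in range(n_kingdoms):
        kingdom = f"K{k + 1:02d}"
        root = _mutate(rng, ancestor, inter_kingdom_divergence / 2.0, mutable)
        for m in range(per_kingdom):
            member = _mutate(rng, root, intra_kingdom_divergence / 2.0, mutable)
            _break_long_runs(rng, member, mutable)
            entries.append((f"{kingdom}_ref{m + 1}", kingdom, member.tobytes().decode()))
    return ReferencePanel(entries, seq_length)


def _max_homopolymer(seq: str) -> int:
    return max((len(list(g)) for _, g in itertools.groupby(seq)), default=0)


def _probe_free(seq: str) -> bool:
    """True when both probes are >=3 mismatches away at every offset."""
    from brine18s.read_qc import find_approx_match

    return not (
        find_approx_match(seq, PROBE_EUK381, 2) or find_approx_match(seq, PROBE_EUK422, 2)
    )


def _homopolymer_indels(
    rng: np.random.Generator, seq: str, rate: float, protected: list[tuple[int, int]]
) -> str:
    """Apply +/-1 indels at homopolymer runs >=3 nt outside protected windows."""
    out: list[str] = []
    pos = 0
    for base, group in itertools.groupby(seq):
        run = len(list(group))
        n = run
        conserved = any(pos < end and pos + run > start for start, end in protected)
        if run >= 3 and not conserved and rng.random() < rate:
            n = run + (1 if rng.random() < 0.5 else -1)
        out.append(base * n)
        pos += run
    return "".join(out)


def _linear_quality(rng: np.random.Generator, length: int, em: ErrorModel) -> np.ndarray:
    base = np.linspace(em.q_start, em.q_end, num=max(length, 2))[:length]
    jitter = rng.integers(-em.q_jitter, em.q_jitter + 1, size=length)
    return np.clip(np.round(base + jitter), 2, 41).astype(int)


def _violation_plan(n: int, fractions: dict[str, float], rng: np.random.Generator) -> list[str]:
    """Assign at most one violation per read: floor counts, remainder clean."""
    labels = []
    for name in VIOLATION_ORDER:
        labels.extend([name] * int(np.floor(fractions[name] * n)))
    labels.extend([""] * (n - len(labels)))
    return [labels[i] for i in rng.permutation(n)]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    panel: ReferencePanel, config: SimulationConfig
) -> tuple[list[b18io.Read], pd.DataFrame]:
    """Simulate a multiplexed read set; returns (reads, ground truth).

    Ground truth has one row per read: read_id, sample_id, template_id
    (empty for false amplicons) and the planted violation (empty if clean).
    """
    if not panel.entries:
        raise ValueError("reference panel is empty")
    rng = np.random.default_rng(config.seed)
    layout = panel.layout()
    probe_end = layout["euk422"][1]
    min_insert = probe_end + 24
    em = config.error
    barcodes = [b for _, b in config.samples]

    reads: list[b18io.Read] = []
    truth_rows: list[dict] = []
    for sample_id, barcode in config.samples:
        weights = None
        ids = panel.ids
        if config.composition is not None:
            comp = config.composition[sample_id]
            ids = list(comp)
            weights = np.array([comp[t] for t in ids], dtype=float)
            weights = weights / weights.sum()
        plan = _violation_plan(config.n_reads, config._fractions(), rng)
        for i, violation in enumerate(plan):
            read_id = f"{sample_id}_{i:05d}"
            ins_len = int(rng.integers(min_insert, panel.seq_length + 1))
            if violation == NO_PROBE:
                while True:
                    body = _random_seq(rng, ins_len - layout["primer"][1]).tobytes().decode()
                    if _probe_free(body) and _max_homopolymer(body) <= 6:
                        break
                insert = FORWARD_PRIMER_1A + body
                template_id = ""
            else:
                template_id = ids[rng.choice(len(ids), p=weights)] if weights is not None else ids[
                    rng.integers(0, len(ids))
                ]
                template = np.frombuffer(panel.sequence(template_id).encode(), np.uint8)
                mutable = _mutable_mask(panel.seq_length, layout)[:ins_len]
                for _ in range(100):
                    mutated = _mutate(rng, template[:ins_len], em.substitution_rate, mutable)
                    insert = mutated.tobytes().decode()
                    insert = _homopolymer_indels(
                        rng, insert, em.homopolymer_indel_rate, list(layout.values())
                    )
                    if _max_homopolymer(insert) <= 6 and len(insert) >= 150:
                        break
                else:  # pragma: no cover - overwhelmingly unlikely
                    raise RuntimeError("could not generate a clean read")

            bc = barcode
            if violation == SHORT:
                insert = insert[: int(rng.integers(60, 150 - len(barcode)))]
            elif violation == AMBIG:
                chars = list(insert)
                for p in rng.choice(len(chars), size=int(rng.integers(1, 4)), replace=False):
                    chars[p] = "N"
                insert = "".join(chars)
            elif violation == HOMOPOLYMER:
                run = rng.integers(7, 10)
                base = DNA_ALPHABET[rng.integers(0, 4)]
                p = int(rng.integers(probe_end, len(insert) + 1))
                insert = insert[:p] + base * int(run) + insert[p:]
            elif violation == BAD_BARCODE:
                while True:
                    bc = _random_seq(rng, 8).tobytes().decode()
                    if all(sum(a != b for a, b in zip(bc, known)) >= 3 for known in barcodes):
                        break

            seq = bc + insert
            qual = _linear_quality(rng, len(seq), em)
            if violation == LOWQ:
                w = min(50, len(seq))
                start = int(rng.integers(0, len(seq) - w + 1))
                qual[start : start + w] = 10
            if config.reverse_complement_fraction and rng.random() < config.reverse_complement_fraction:
                seq = seq.translate(_COMPLEMENT)[::-1]
                qual = qual[::-1]
            reads.append(b18io.Read(read_id, seq, list(qual)))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample_id": sample_id,
                    "template_id": template_id,
                    "violations": violation,
                }
            )

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order]).set_index("read_id")
    return reads, truth


def write_fixture(
    reads: Sequence[b18io.Read],
    ground_truth: pd.DataFrame,
    mapping: dict[str, str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write reads.fastq, mapping.tsv and ground_truth.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq": b18io.write_fastq(reads, out / "reads.fastq"),
        "mapping": b18io.write_mapping(mapping, out / "mapping.tsv"),
        "ground_truth": b18io.write_table(
            ground_truth, out / "ground_truth.tsv", index_label="read_id"
        ),
    }
    return paths


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = b18io.read_table(path)
    return df.fillna("")
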
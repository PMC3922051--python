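"""End-to-end orchestration: simulate -> QC -> cluster -> diversity/classify -> ordinate.

A run is driven by a single :class:`RunConfig` (loadable from YAML) and a
master seed.  Per-stage seeds are derived from the master seed by hashing
``"{master_seed}:{stage_name}"`` with BLAKE2b and taking the first 4 bytes
modulo 2^31, so any stage can be re-run in isolation with the same
randomness.  All tables are TSV with a ``#`` header line, trees are Newick,
sequences FASTA/FASTQ; re-running an identical config reproduces
byte-identical outputs, which the manifest records as SHA-256 digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from brine18s import io as b18io
from brine18s import synthetic_data as synth
from brine18s.community_ordination import bray_curtis, group_separation, pcoa
from brine18s.diversity_metrics import diversity_table
from brine18s.otu_clustering import (
    OTUTable,
    cluster_greedy,
    dereplicate,
    drop_singletons,
    pick_representatives,
)
from brine18s.phylo_classify import (
    clade_abundance_matrix,
    classify_representatives,
    write_newick,
)
from brine18s.read_qc import ProbeSet, QCParams, run_qc
from brine18s.synthetic_data import ReferencePanel


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # either a simulation block or pre-existing input paths
    simulate: dict | None = None
    fastq: str | None = None
    mapping: str | None = None
    references: str | None = None
    panel: dict | None = None  # panel generation parameters when simulating
    qc: dict = dataclasses.field(default_factory=dict)
    levels: tuple[float, float] = (0.03, 0.20)
    bootstrap: int = 100
    min_support: float = 0.5
    drop_ids: str | None = None
    k_axes: int = 2

    def __post_init__(self) -> None:
        for level in self.levels:
            if not 0 < level < 1:
                raise ValueError(f"clustering level {level} outside (0, 1)")
        if self.simulate is None:
            for field in ("fastq", "mapping", "references"):
                value = getattr(self, field)
                if value is None:
                    raise ValueError(f"config needs either a 'simulate' block or '{field}'")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{field} path does not exist: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    # --- inputs: simulate or load -------------------------------------
    if config.simulate is not None:
        panel_kwargs = dict(config.panel or {})
        panel_kwargs.setdefault("seed", stage_seed(config.seed, "panel"))
        panel = synth.generate_reference_panel(**panel_kwargs)
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        if sim_kwargs.get("composition") == "archetypes":
            sim_kwargs["composition"], _ = synth.archetype_compositions(panel)
        sim_config = synth.default_config(**sim_kwargs)
        reads, truth = synth.simulate_reads(panel, sim_config)
        mapping = sim_config.mapping()
        sim_dir = out / "simulate"
        paths = synth.write_fixture(reads, truth, mapping, sim_dir)
        panel.to_fasta(sim_dir / "references.fasta")
        manifest["stages"]["simulate"] = {
            "n_reads": len(reads),
            "n_samples": len(mapping),
            "panel_size": len(panel.entries),
        }
        for key, p in paths.items():
            manifest["outputs"][f"simulate/{Path(p).name}"] = _sha256(Path(p))
    else:
        reads = b18io.read_fastq(config.fastq)
        mapping = b18io.read_mapping(config.mapping)
        panel = ReferencePanel.from_fasta(config.references)
        manifest["stages"]["load"] = {"n_reads": len(reads), "n_samples": len(mapping)}

    # --- QC ------------------------------------------------------------
    params = QCParams(**config.qc)
    qualified, report = run_qc(reads, mapping, ProbeSet(), params)
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    b18io.write_table(report, qc_dir / "qc_report.tsv", index_label="sample")
    for sample, sample_reads in qualified.items():
        b18io.write_fasta(
            ((r.id, r.seq) for r in sample_reads), qc_dir / f"{sample}.fasta"
        )
    n_qualified = sum(len(v) for v in qualified.values())
    n_rejected = len(reads) - n_qualified
    if report["input"].sum() != len(reads):
        raise RuntimeError("QC conservation violated: input counts do not add up")
    manifest["stages"]["qc"] = {
        "input": len(reads),
        "qualified": n_qualified,
        "rejected": n_rejected,
    }
    manifest["outputs"]["qc/qc_report.tsv"] = _sha256(qc_dir / "qc_report.tsv")

    derep = dereplicate(qualified)

    # --- clustering at the diversity level -----------------------------
    fine_level = min(config.levels)
    table_fine = pick_representatives(cluster_greedy(derep, fine_level))
    _check_conservation(table_fine, n_qualified, "fine-level clustering")
    div = diversity_table(table_fine, seed=stage_seed(config.seed, "rarefaction"))
    _write_otu_outputs(table_fine, out / f"otu_{_pct(fine_level)}", manifest)
    b18io.write_table(div, out / "diversity.tsv", index_label="sample")
    manifest["outputs"]["diversity.tsv"] = _sha256(out / "diversity.tsv")
    manifest["stages"]["diversity"] = {
        "otus": len(table_fine.otus),
        "rarefaction_depth": int(div["rarefaction_depth"].iloc[0]),
    }

    # --- clustering at the placement level ------------------------------
    coarse_level = max(config.levels)
    table_coarse = pick_representatives(cluster_greedy(derep, coarse_level))
    _check_conservation(table_coarse, n_qualified, "coarse-level clustering")
    table_coarse, n_singletons = drop_singletons(table_coarse)
    _write_otu_outputs(table_coarse, out / f"otu_{_pct(coarse_level)}", manifest)
    manifest["stages"]["cluster_coarse"] = {
        "otus": len(table_coarse.otus),
        "singletons_removed": n_singletons,
    }

    # --- phylogenetic classification ------------------------------------
    drop_ids = None
    if config.drop_ids:
        drop_ids = {
            line.strip()
            for line in Path(config.drop_ids).read_text().splitlines()
            if line.strip()
        }
    reps = {otu.otu_id: otu.representative for otu in table_coarse.otus}
    classify_dir = out / "classify"
    classify_dir.mkdir(exist_ok=True)
    result = classify_representatives(
        reps,
        panel,
        n_replicates=config.bootstrap,
        seed=stage_seed(config.seed, "bootstrap"),
        min_support=config.min_support,
        drop_ids=drop_ids,
    )
    msa = result["msa"]
    b18io.write_fasta(zip(msa.ids, msa.rows), classify_dir / "msa.fasta")
    write_newick(result["tree"], classify_dir / "tree.nwk")
    b18io.write_table(
        result["assignments"], classify_dir / "clade_assignments.tsv", index_label="otu_id"
    )
    kept = table_coarse
    if drop_ids:
        kept = OTUTable(
            table_coarse.level,
            [o for o in table_coarse.otus if o.otu_id not in drop_ids],
            table_coarse.samples,
        )
    clade_matrix = clade_abundance_matrix(result["assignments"], kept)
    b18io.write_table(clade_matrix, classify_dir / "clade_matrix.tsv", index_label="sample")
    for name in ("msa.fasta", "tree.nwk", "clade_assignments.tsv", "clade_matrix.tsv"):
        manifest["outputs"][f"classify/{name}"] = _sha256(classify_dir / name)
    manifest["stages"]["classify"] = {
        "queries": len(result["assignments"]),
        "novel": int((result["assignments"]["clade_label"] == "NOVEL").sum()),
        "clades": clade_matrix.shape[1],
    }

    # --- ordination ------------------------------------------------------
    dm = bray_curtis(clade_matrix)
    ordination = pcoa(dm, k=min(config.k_axes, len(dm) - 1))
    ord_dir = out / "ordination"
    ord_dir.mkdir(exist_ok=True)
    b18io.write_table(dm, ord_dir / "braycurtis.tsv", index_label="sample")
    b18io.write_table(
        ordination.coordinates, ord_dir / "ordination.tsv", index_label="sample"
    )
    axes = pd.DataFrame(
        {
            "eigenvalue": ordination.eigenvalues[: ordination.coordinates.shape[1]],
            "variance_fraction": ordination.proportion_explained,
        },
        index=list(ordination.coordinates.columns),
    )
    b18io.write_table(axes, ord_dir / "axes.tsv", index_label="axis")
    for name in ("braycurtis.tsv", "ordination.tsv", "axes.tsv"):
        manifest["outputs"][f"ordination/{name}"] = _sha256(ord_dir / name)
    manifest["stages"]["ordination"] = {
        "axes": int(ordination.coordinates.shape[1]),
        "variance_fraction_1_2": float(ordination.proportion_explained[:2].sum()),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _pct(level: float) -> str:
    return f"{int(round(level * 100)):02d}"


def _check_conservation(table: OTUTable, n_qualified: int, stage: str) -> None:
    if table.total_count != n_qualified:
        raise RuntimeError(
            f"{stage}: OTU counts ({table.total_count}) != qualified reads ({n_qualified})"
        )


def _write_otu_outputs(table: OTUTable, prefix: Path, manifest: dict) -> None:
    prefix.mkdir(parents=True, exist_ok=True)
    counts = table.count_matrix()
    b18io.write_table(counts, prefix / "otu_counts.tsv", index_label="otu_id")
    members = pd.DataFrame(
        [
            {"otu_id": otu.otu_id, "sequence": seq, "count": sum(c.values())}
            for otu in table.otus
            for seq, c in otu.members
        ]
    )
    if members.empty:
        members = pd.DataFrame(columns=["otu_id", "sequence", "count"])
    members = members.set_index("otu_id")
    b18io.write_table(members, prefix / "otu_members.tsv", index_label="otu_id")
    reps = [
        (otu.otu_id, otu.representative or otu.centroid) for otu in table.otus
    ]
    b18io.write_fasta(reps, prefix / "representatives.fasta")
    for name in ("otu_counts.tsv", "otu_members.tsv", "representatives.fasta"):
        manifest["outputs"][f"{prefix.name}/{name}"] = _sha256(prefix / name)
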
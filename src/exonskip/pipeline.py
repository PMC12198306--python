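"""End-to-end orchestration: simulate -> design -> count -> qc -> report.

The pipeline fixes the on-disk contract (tab-separated tables with a single
header line, JSON summaries) and records a :class:`RunManifest` with a
content digest for every output, so a rerun with identical configuration
and inputs reproduces the digests bit for bit.  All randomness flows from
the single seed in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import expression_report as er
from . import junction_quant as jq
from . import read_qc as rq
from . import simulate as sim
from .gene_models import splice_transcript

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("exonskip")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    logs: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, path: str) -> None:
        with open(path, "rb") as fh:
            self.outputs[os.path.basename(path)] = hashlib.sha256(
                fh.read()
            ).hexdigest()

    def write(self, out_dir: str) -> str:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)
        return path


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        if path.endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _species_table(config: dict) -> pd.DataFrame:
    spec = config.get("species_table")
    if isinstance(spec, str):
        if not os.path.exists(spec):
            raise FileNotFoundError(f"species table not found: {spec}")
        return pd.read_csv(spec, sep="\t")
    return pd.DataFrame(spec)


def run_pipeline(config: dict, out_dir: str) -> RunManifest:
    """Run simulate -> design -> count -> qc -> report from one config dict.

    Config keys: ``seed`` (int), ``species_table`` (TSV path or inline row
    list with species/skipping/depth_tier), ``min_reads`` (presence
    threshold, default 1), plus optional generator overrides ``pi_s``,
    ``error_rate``, ``chimera_fraction``.  Outputs land in ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config_digest=_digest(config), seed=seed)
    stage = "configure"
    try:
        table = _species_table(config)
        scenario = sim.scenario_from_table(
            table,
            seed=seed,
            pi_s_when_present=float(config.get("pi_s", 0.3)),
            error_rate=float(config.get("error_rate", 0.005)),
            chimera_fraction=float(config.get("chimera_fraction", 0.03)),
        )

        stage = "simulate"
        manifest.stages.append(stage)
        reads, truth = sim.simulate_reads(scenario)
        fq = os.path.join(out_dir, "reads.fastq")
        sim.write_fastq(reads, fq)
        truth_path = os.path.join(out_dir, "truth.tsv")
        truth.to_csv(truth_path, sep="\t", index=False)
        manifest.record(fq)
        manifest.record(truth_path)
        manifest.logs[stage] = f"{len(reads)} reads over {len(scenario.species)} species"

        stage = "design"
        manifest.stages.append(stage)
        queries, meta = design_all_queries(scenario)
        q_path = os.path.join(out_dir, "ejrna.tsv")
        pd.DataFrame(
            [
                {
                    "query_id": q.query_id, "gene": q.gene_id,
                    "type": q.junction_type, "sequence": q.sequence,
                }
                for q in queries
            ]
        ).to_csv(q_path, sep="\t", index=False)
        manifest.record(q_path)
        manifest.logs[stage] = f"{len(queries)} junction queries"

        stage = "count"
        manifest.stages.append(stage)
        counts, matched = jq.count_junction_reads(reads, queries)
        c_path = os.path.join(out_dir, "counts.tsv")
        pd.DataFrame(
            sorted(counts.items()), columns=["query_id", "reads"]
        ).to_csv(c_path, sep="\t", index=False)
        manifest.record(c_path)
        manifest.logs[stage] = f"{sum(counts.values())} matched read-query pairs"

        stage = "qc"
        manifest.stages.append(stage)
        qc_rows = classify_all(scenario, meta, matched)
        qc_path = os.path.join(out_dir, "qc.tsv")
        qc_rows.to_csv(qc_path, sep="\t", index=False)
        summary = rq.qc_summary(
            (rq.QcCategory(l) for l in qc_rows["category"]),
            qc_rows["read_length"],
        )
        s_path = os.path.join(out_dir, "qc_summary.json")
        with open(s_path, "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest.record(qc_path)
        manifest.record(s_path)
        manifest.logs[stage] = (
            f"{summary['n_reads']} matched reads, "
            f"{summary['fractions_percent']['clean']}% clean"
        )

        stage = "report"
        manifest.stages.append(stage)
        expr, presence = expression_tables(
            scenario, counts, meta, min_reads=int(config.get("min_reads", 1))
        )
        e_path = os.path.join(out_dir, "expression.tsv")
        expr.to_csv(e_path, sep="\t", index=False)
        p_path = os.path.join(out_dir, "presence.tsv")
        presence.to_csv(p_path, sep="\t", index=False)
        depth_table, assoc = er.depth_report(
            dict(zip(presence["species"], presence["actb_reads"])),
            dict(zip(presence["species"], presence["s_present"])),
        )
        d_path = os.path.join(out_dir, "depth.json")
        with open(d_path, "w") as fh:
            json.dump(
                {
                    "association": assoc,
                    "table": depth_table.to_dict(orient="records"),
                },
                fh, indent=1, default=str,
            )
        for p in (e_path, p_path, d_path):
            manifest.record(p)
        n_both = int((presence["s_present"] & presence["l_present"]).sum())
        manifest.logs[stage] = (
            f"{n_both}/{len(presence)} species with both isoforms; "
            f"depth association {assoc:.3f}"
        )
    except Exception as exc:  # noqa: BLE001 — manifest must name the stage
        manifest.failed_stage = stage
        manifest.logs[stage] = f"FAILED: {exc}"
        manifest.write(out_dir)
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out_dir)
    return manifest


# ---------------------------------------------------------------------------
# stage helpers (shared by the CLI and the library API)
# ---------------------------------------------------------------------------

@dataclass
class QueryMeta:
    """Bookkeeping linking each query to its species, isoform and junction."""

    species_id: str
    fixture: sim.GeneFixture
    expected_isoform: dict[str, str] = field(default_factory=dict)
    containment: dict[str, bool] = field(default_factory=dict)  # has cassette exon


def design_all_queries(
    scenario: sim.SimulationScenario,
) -> tuple[list[jq.EjRNA], dict[str, QueryMeta]]:
    """Inclusion, skipping and control queries for every scenario species."""
    ci = scenario.gene_config.cassette_index
    queries: list[jq.EjRNA] = []
    meta: dict[str, QueryMeta] = {}
    for si, spec in enumerate(scenario.species):
        fixture = scenario.fixture_for(si)
        m = QueryMeta(species_id=spec.species_id, fixture=fixture)
        target = fixture.models[f"{spec.species_id}_drd2"]
        ex = [e.exon_id for e in target.exons]
        seqs = fixture.sequences
        incl = jq.design_ejrna(target, ex[ci - 1], ex[ci], seqs)
        skip = jq.design_ejrna(target, ex[ci - 1], ex[ci + 1], seqs)
        control = fixture.models[f"{spec.species_id}_actb"]
        cex = [e.exon_id for e in control.exons]
        ctl = jq.design_ejrna(
            control, cex[2], cex[3], seqs, junction_type="control"
        )
        queries += [incl, skip, ctl]
        m.expected_isoform = {
            incl.query_id: f"{target.gene_id}_L",
            skip.query_id: f"{target.gene_id}_S",
            ctl.query_id: f"{control.gene_id}_t",
        }
        m.containment = {incl.query_id: True, skip.query_id: False}
        for q in (incl, skip, ctl):
            meta[q.query_id] = m
    return queries, meta


def classify_all(
    scenario: sim.SimulationScenario,
    meta: dict[str, QueryMeta],
    matched: list[jq.MatchedRead],
) -> pd.DataFrame:
    """QC every matched read against its species' reference sets."""
    vectors, foreign = scenario.pools()
    rows = []
    for m in matched:
        qm = meta[m.query_id]
        fixture = qm.fixture
        expected = fixture.transcripts[
            qm.expected_isoform.get(
                m.query_id, f"{qm.species_id}_actb_t"
            )
        ]
        gene_id = m.query_id.split(":")[0]
        same_gene = {
            iso_id: t for iso_id, t in fixture.transcripts.items()
            if fixture.isoforms[iso_id].gene_id == gene_id
        }
        same_species = {
            iso_id: t for iso_id, t in fixture.transcripts.items()
            if fixture.isoforms[iso_id].gene_id != gene_id
        }
        cat = rq.classify_matched_read(
            m, expected, same_gene, same_species, foreign, vectors
        )
        rows.append({
            "read_id": m.read_id,
            "query_id": m.query_id,
            "category": cat.label,
            "read_length": len(m.read_sequence),
            "evidence": json.dumps(
                {k: v for k, v in cat.evidence.items() if k != "reference_hits"},
                default=str,
            ),
        })
    return pd.DataFrame(
        rows, columns=["read_id", "query_id", "category", "read_length", "evidence"]
    )


def expression_tables(
    scenario: sim.SimulationScenario,
    counts: dict[str, int],
    meta: dict[str, QueryMeta],
    min_reads: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species L/S subtotals, Actb-normalised ratios and presence calls."""
    expr_rows, presence_rows = [], []
    for spec in scenario.species:
        sp = spec.species_id
        sp_meta = next(m for m in meta.values() if m.species_id == sp)
        sp_queries = {
            q: c for q, c in counts.items() if meta[q].species_id == sp
        }
        ctl_count = sum(
            c for q, c in sp_queries.items()
            if q not in sp_meta.containment
        )
        gene_counts = {
            q: c for q, c in sp_queries.items() if q in sp_meta.containment
        }
        L, S = er.aggregate_isoforms(gene_counts, sp_meta.containment)
        for cls, raw in (("L", L), ("S", S)):
            expr_rows.append({
                "species": sp,
                "gene": f"{sp}_drd2",
                "isoform_class": cls,
                "raw_count": raw,
                "actb_count": ctl_count,
                "log10_ratio": (
                    er.normalized_expression(raw, ctl_count)
                    if ctl_count > 0 else None
                ),
                "present": er.presence_call(raw, min_reads),
            })
        presence_rows.append({
            "species": sp,
            "actb_reads": ctl_count,
            "l_count": L,
            "s_count": S,
            "l_present": er.presence_call(L, min_reads),
            "s_present": er.presence_call(S, min_reads),
        })
    return (
        pd.DataFrame(expr_rows),
        pd.DataFrame(presence_rows),
    )
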
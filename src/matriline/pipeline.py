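"""End-to-end analysis: alignment -> haplotypes -> diversity -> network ->
tree/swaps -> dating, from one config, with a reproducible report bundle.

Outputs written to the configured directory:

* ``haplotypes.tsv``       haplotype table
* ``sites.tsv``            per-column site classification
* ``diversity.tsv``        per-species h and pi summary
* ``network.graphml`` / ``network_edges.tsv``  median-joining network
* ``tree.nwk``             neighbor-joining tree over haplotypes
* ``swaps.tsv``            flagged field-label/matriline conflicts
* ``dating.tsv``           distance-based ages per configured clade pair
* ``summary.json``         every parameter, seed and headline number
* ``MANIFEST``             per-stage success/failure record

Re-running with the same config and seeds reproduces every output
byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .distances import (
    RateCalibration, date_divergence, distance_matrix, group_divergence,
)
from .diversity import species_diversity_table
from .haplotypes import (
    base_composition, classify_sites, collapse_haplotypes, shared_haplotypes,
)
from .network import export_network, median_join
from .seq_io import (
    read_alignment, read_metadata, write_exclusion_report,
)
from .trees import detect_swaps, nj_tree, test_monophyly, write_newick

logger = logging.getLogger(__name__)


class PipelineInputError(ValueError):
    pass


@dataclass
class CladePair:
    """A named d_xy / dating contrast between two sets of species labels."""

    label: str
    species_a: tuple[str, ...]
    species_b: tuple[str, ...]


@dataclass
class PipelineConfig:
    fasta: str
    metadata: str
    outdir: str
    filter_mode: str = "complete_deletion"
    epsilon: int = 0
    n_bootstrap: int = 1000
    n_resamples: int = 0
    seed: int = 0
    net_distance: bool = False
    clade_pairs: list[CladePair] = field(default_factory=list)
    rates: RateCalibration = field(default_factory=RateCalibration)
    outgroup: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        pairs = [
            CladePair(
                label=p["label"],
                species_a=tuple(p["species_a"]),
                species_b=tuple(p["species_b"]),
            )
            for p in raw.pop("clade_pairs", [])
        ]
        rates = RateCalibration(**raw.pop("rates", {}))
        return cls(clade_pairs=pairs, rates=rates, **raw)

    def to_dict(self) -> dict:
        return {
            "fasta": str(self.fasta),
            "metadata": str(self.metadata),
            "outdir": str(self.outdir),
            "filter_mode": self.filter_mode,
            "epsilon": self.epsilon,
            "n_bootstrap": self.n_bootstrap,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "net_distance": self.net_distance,
            "outgroup": list(self.outgroup),
            "clade_pairs": [
                {
                    "label": p.label,
                    "species_a": list(p.species_a),
                    "species_b": list(p.species_b),
                }
                for p in self.clade_pairs
            ],
            "rates": {
                "mu_low": self.rates.mu_low,
                "mu_mid": self.rates.mu_mid,
                "mu_fast": self.rates.mu_fast,
            },
        }


@dataclass
class PipelineResult:
    outdir: Path
    summary: dict
    swaps: object
    failed_stage: str | None = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None


def _default_clade_pairs(metadata) -> list[CladePair]:
    """All species-vs-species contrasts with >= 1 individual each."""
    species = metadata.species_labels()
    return [
        CladePair(label=f"{a} X {b}", species_a=(a,), species_b=(b,))
        for i, a in enumerate(species)
        for b in species[i + 1:]
    ]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage; on a stage error, keep earlier outputs and record
    the failing stage in MANIFEST (the CLI then exits non-zero)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {
        "package": "matriline",
        "version": __version__,
        "parameters": config.to_dict(),
    }

    def done(stage: str) -> None:
        manifest.append(f"{stage}\tok")

    stage = "read_inputs"
    try:
        for path in (config.fasta, config.metadata):
            if not Path(path).exists():
                raise PipelineInputError(f"input file not found: {path}")
        alignment = read_alignment(config.fasta, filter_mode=config.filter_mode)
        metadata = read_metadata(config.metadata, alignment)
        write_exclusion_report(alignment, outdir / "excluded_columns.tsv")
        summary["n_individuals"] = alignment.n
        summary["alignment_length"] = alignment.length
        summary["n_excluded_columns"] = len(alignment.excluded_columns)
        done(stage)

        stage = "haplotypes"
        table = collapse_haplotypes(alignment)
        table.write_tsv(outdir / "haplotypes.tsv")
        sites = classify_sites(alignment)
        sites.write_tsv(outdir / "sites.tsv")
        comp = base_composition(alignment)
        shared = shared_haplotypes(table, metadata)
        summary["n_haplotypes"] = len(table)
        summary["n_variable_sites"] = sites.n_variable
        summary["n_informative_sites"] = sites.n_informative
        summary["base_composition_pct"] = {
            b: round(100 * f, 1) for b, f in comp.items()
        }
        summary["shared_haplotypes"] = [
            {"haplotype": h, "species": list(sp)} for h, sp in shared
        ]
        done(stage)

        stage = "diversity"
        div = species_diversity_table(
            alignment, metadata,
            n_bootstrap=config.n_bootstrap,
            n_resamples=config.n_resamples,
            seed=config.seed,
        )
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False, float_format="%.6g")
        done(stage)

        stage = "network"
        network = median_join(table, epsilon=config.epsilon, metadata=metadata)
        export_network(network, outdir / "network.graphml", fmt="graphml")
        export_network(network, outdir / "network_edges.tsv", fmt="tsv")
        summary["network"] = {
            "n_observed": len(network.observed_ids),
            "n_medians": len(network.median_ids),
            "n_edges": network.graph.number_of_edges(),
            "converged": network.converged,
        }
        done(stage)

        stage = "tree"
        hap_alignment = table.to_alignment()
        tree = None
        if len(table) >= 3:
            dm = distance_matrix(hap_alignment)
            outgroup_haps = [
                table.haplotype_of(i) for i in config.outgroup
            ] if config.outgroup else None
            tree = nj_tree(dm, outgroup_ids=outgroup_haps)
            write_newick(tree, outdir / "tree.nwk")
        monophyly = {}
        for sp, ids in metadata.by_species().items():
            if len(ids) < 2:
                continue
            res = test_monophyly(network, table, metadata, sp)
            monophyly[sp] = res.is_monophyletic
        summary["monophyly_network"] = monophyly
        done(stage)

        stage = "swaps"
        report = detect_swaps(tree, network, table, metadata)
        report.write_tsv(outdir / "swaps.tsv")
        summary["n_swaps_confirmed"] = len(report.confirmed())
        summary["n_swaps_total"] = len(report)
        done(stage)

        stage = "dating"
        pairs = config.clade_pairs or _default_clade_pairs(metadata)
        by_species = metadata.by_species()
        rows = []
        for k, pair in enumerate(pairs):
            ids_a = [i for sp in pair.species_a for i in by_species.get(sp, [])]
            ids_b = [i for sp in pair.species_b for i in by_species.get(sp, [])]
            if not ids_a or not ids_b:
                raise PipelineInputError(
                    f"clade pair {pair.label!r} references unsampled species"
                )
            if set(ids_a) & set(ids_b):
                raise PipelineInputError(f"clade pair {pair.label!r} is not disjoint")
            div_xy = group_divergence(
                alignment, ids_a, ids_b,
                n_bootstrap=config.n_bootstrap,
                seed=config.seed + k,
                net=config.net_distance,
                label=pair.label,
            )
            age = date_divergence(div_xy, config.rates)
            rows.append(
                (pair.label, div_xy.d_xy, div_xy.se, age.t_mid, age.t_low, age.t_high)
            )
        with open(outdir / "dating.tsv", "w", encoding="utf-8") as fh:
            fh.write("clade_pair\td_xy\tse\tt_mid\tt_low\tt_high\n")
            for label, d, se, tm, tl, th in rows:
                fh.write(
                    f"{label}\t{d:.6f}\t{se:.6f}\t{tm:.0f}\t{tl:.0f}\t{th:.0f}\n"
                )
        summary["dating"] = [
            {"pair": label, "d_xy": d, "se": se,
             "t_mid": tm, "t_low": tl, "t_high": th}
            for label, d, se, tm, tl, th in rows
        ]
        done(stage)
    except Exception as exc:  # record the failing stage, keep partial outputs
        manifest.append(f"{stage}\tFAILED\t{exc}")
        (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        return PipelineResult(
            outdir=outdir, summary=summary, swaps=None, failed_stage=stage
        )

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return PipelineResult(outdir=outdir, summary=summary, swaps=report)
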
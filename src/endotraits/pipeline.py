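"""End-to-end orchestration: plate -> traits -> classification -> statistics
-> phylogenetic signal, with a reproducibility manifest.

Every stage writes plain CSV/TSV; the manifest records seeds, thresholds,
input checksums and the package version so a run can be reproduced
byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from . import assemblage as asm
from . import biolog
from . import community_stats as cstats
from . import phylosignal
from .trees import Phylogeny, load_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    plate_csv: str
    out_dir: str
    metadata_csv: str | None = None
    tree_newick: str | None = None
    taxonomy_csv: str | None = None
    use_threshold: float = biolog.USE_THRESHOLD
    common_frac: float = 0.5
    mixture_seed: int = 0
    n_starts: int = 10
    manual_cutoff: float | None = None
    n_perm: int = 999
    min_tips: int = 5
    signal_seed: int = 0
    assume_branch_length: float | None = None

    def validate(self) -> None:
        if not 0 <= self.common_frac:
            raise ValueError("common_frac must be >= 0")
        if self.n_perm < 1 or self.min_tips < 2 or self.n_starts < 1:
            raise ValueError("n_perm, min_tips and n_starts must be positive")
        for name in ("plate_csv", "metadata_csv", "tree_newick",
                     "taxonomy_csv"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path}")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    """Decorator tagging stage failures with the stage name."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("traits")
def _run_traits(config: RunConfig, out: str):
    plate = biolog.read_plate(config.plate_csv)
    traits = biolog.build_trait_table(
        plate, threshold=config.use_threshold, min_frac=config.common_frac
    )
    traits.write(
        os.path.join(out, "traits.csv"),
        sg_csv=os.path.join(out, "sg.csv"),
        use_csv=os.path.join(out, "use.csv"),
    )
    return plate, traits


@_stage("classify")
def _run_classify(config: RunConfig, traits, metadata, out: str):
    values = traits.summary["mean_sg_common"]
    fit = asm.fit_mixture(
        values, seed=config.mixture_seed, n_starts=config.n_starts
    )
    cutoff = config.manual_cutoff if config.manual_cutoff is not None else fit.cutoff
    if cutoff is None:
        raise ValueError("mixture yielded no cutoff; pass manual_cutoff")
    assignment = asm.assign(values, cutoff)
    fit.to_json(os.path.join(out, "mixture.json"))
    table = pd.DataFrame(
        {"mean_sg_common": values, "assemblage": assignment.labels}
    )
    table.to_csv(os.path.join(out, "assemblages.csv"), index_label="isolate_id")
    return fit, assignment


@_stage("stats")
def _run_stats(config: RunConfig, traits, assignment, metadata, out: str):
    rows = []
    labels = assignment.labels
    width = traits.summary["niche_width"]
    growth = traits.summary["mean_sg_common"]
    slow, fast = labels == "slow", labels == "fast"

    def add(test, groups, stat, df, p, extra=""):
        rows.append({"test": test, "groups": groups, "statistic": stat,
                     "df": df, "p": p, "note": extra})

    if slow.sum() >= 2 and fast.sum() >= 2:
        for variant in ("welch", "pooled"):
            r = cstats.t_test(growth[slow], growth[fast], variant=variant)
            add(f"t_{variant}", "mean_sg_common slow vs fast",
                r.statistic, r.df, r.pvalue)
            r = cstats.t_test(width[slow], width[fast], variant=variant)
            add(f"t_{variant}", "niche_width slow vs fast",
                r.statistic, r.df, r.pvalue)
        chi2, df, p = cstats.fligner_killeen(
            {"slow": width[slow], "fast": width[fast]}
        )
        add("fligner_killeen", "niche_width variance slow vs fast",
            chi2, df, p)
    else:
        logger.warning("one assemblage has < 2 isolates; group stats skipped")

    richness = None
    if metadata is not None:
        cells, summary, tests = cstats.richness_per_leaf(metadata)
        cells.to_csv(os.path.join(out, "richness.csv"), index=False)
        for variant, r in tests.items():
            add(f"t_{variant}", "otu richness per leaf by method",
                r.statistic, r.df, r.pvalue,
                extra="; ".join(
                    f"{m} {row['mean']:.2f}+/-{row['std']:.2f}"
                    for m, row in summary.iterrows()
                ))
        if "method" in metadata.columns:
            by_method = metadata.set_index("isolate_id")["method"]
            for variant in ("welch", "pooled"):
                g = growth.groupby(by_method.reindex(growth.index))
                samples = {m: v for m, v in g}
                if len(samples) == 2:
                    a, b = samples.values()
                    r = cstats.t_test(a, b, variant=variant)
                    add(f"t_{variant}", "mean_sg_common by method",
                        r.statistic, r.df, r.pvalue)
        richness = cells
    stats = pd.DataFrame(rows)
    stats.to_csv(os.path.join(out, "stats.tsv"), sep="\t", index=False)
    return stats, richness


@_stage("fisher")
def _run_fisher(config: RunConfig, assignment, taxonomy, out: str):
    tables = {}
    for rank in ("class", "order"):
        if rank not in taxonomy.columns:
            continue
        joined = pd.DataFrame({
            "taxon": taxonomy[rank].reindex(assignment.labels.index),
            "assemblage": assignment.labels,
        }).dropna()
        counts = (
            joined.groupby(["taxon", "assemblage"]).size().unstack(fill_value=0)
            .reindex(columns=["slow", "fast"], fill_value=0)
        )
        if counts.shape[0] < 2:
            logger.info("fewer than 2 %s groups; Fisher table skipped", rank)
            continue
        result = cstats.rowwise_fisher(counts)
        result.to_csv(os.path.join(out, f"fisher_{rank}.tsv"), sep="\t")
        tables[rank] = result
    return tables


@_stage("signal")
def _run_signal(config: RunConfig, traits, taxonomy, assignment, out: str):
    tree = Phylogeny.from_newick(
        config.tree_newick, assume_length=config.assume_branch_length
    )
    tree = tree.restrict_to(traits.sg.index)
    groups: dict[str, set[str]] = {}
    if taxonomy is not None:
        for rank in ("class", "order"):
            if rank in taxonomy.columns:
                for name, members in taxonomy.groupby(rank).groups.items():
                    groups[str(name)] = set(members)
    else:
        logger.info("no taxonomy supplied; signal scan restricted to the "
                    "entire tree")
    results = phylosignal.signal_scan(
        tree, traits.sg, groups=groups, n_perm=config.n_perm,
        seed=config.signal_seed, min_tips=config.min_tips,
        assemblages=assignment.labels,
    )
    summary = phylosignal.summarize_scan(results)
    results.to_csv(os.path.join(out, "signal_results.tsv"), sep="\t",
                   index=False)
    summary.to_csv(os.path.join(out, "signal_summary.tsv"), sep="\t",
                   index=False)
    return results, summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the supplied inputs allow; return key results.

    Always: trait table and mixture classification. With metadata:
    richness and method contrasts plus per-taxon Fisher tables. With a
    tree: the phylogenetic-signal scan (per-resource K and RT p at each
    taxonomic level).
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    plate, traits = _run_traits(config, out)

    metadata = None
    if config.metadata_csv:
        metadata = pd.read_csv(config.metadata_csv, dtype=str)
        plate_ids = set(plate.isolates)
        meta_ids = set(metadata["isolate_id"])
        unmatched = sorted(plate_ids - meta_ids)
        if unmatched:
            raise ValueError(
                f"isolates on plate but not in metadata: {unmatched[:10]}"
                + ("..." if len(unmatched) > 10 else "")
            )

    taxonomy = None
    if config.taxonomy_csv:
        taxonomy = load_taxonomy(config.taxonomy_csv)
    elif metadata is not None and {"class", "order"} <= set(metadata.columns):
        taxonomy = metadata.set_index("isolate_id")[
            [c for c in ("otu_id", "class", "order") if c in metadata.columns]
        ]

    fit, assignment = _run_classify(config, traits, metadata, out)
    stats, richness = _run_stats(config, traits, assignment, metadata, out)

    fisher = {}
    if taxonomy is not None:
        fisher = _run_fisher(config, assignment, taxonomy, out)

    signal = summary = None
    if config.tree_newick:
        signal, summary = _run_signal(config, traits, taxonomy, assignment, out)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs_sha256": {
            name: _sha256(path)
            for name, path in (
                ("plate_csv", config.plate_csv),
                ("metadata_csv", config.metadata_csv),
                ("tree_newick", config.tree_newick),
                ("taxonomy_csv", config.taxonomy_csv),
            )
            if path
        },
        "n_isolates": len(plate.isolates),
        "n_resources": len(plate.resources),
        "n_common_resources": len(traits.common),
        "cutoff": assignment.cutoff,
        "assemblage_counts": assignment.counts(),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "plate": plate,
        "traits": traits,
        "mixture": fit,
        "assignment": assignment,
        "stats": stats,
        "richness": richness,
        "fisher": fisher,
        "signal": signal,
        "signal_summary": summary,
        "manifest": manifest,
    }
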
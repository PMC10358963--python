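"""Run the whole pipeline end to end on generated inputs.

Simulates a community, writes its files, and runs every stage: trait
scoring, mixture classification, group statistics, per-taxon Fisher
tables, and the phylogenetic-signal scan at entire/class/order levels.
"""
import tempfile
from pathlib import Path

from endotraits import CommunitySpec, RunConfig, run_pipeline, simulate_community

with tempfile.TemporaryDirectory() as tmp:
    paths = simulate_community(CommunitySpec(seed=1)).write(Path(tmp) / "in")
    result = run_pipeline(RunConfig(
        plate_csv=paths["plate"], metadata_csv=paths["metadata"],
        tree_newick=paths["tree"], taxonomy_csv=paths["taxonomy"],
        out_dir=str(Path(tmp) / "out"), n_perm=199,
    ))

    m = result["manifest"]
    print(f"isolates {m['n_isolates']}, resources {m['n_resources']}, "
          f"common {m['n_common_resources']}, cutoff {m['cutoff']:.3f}, "
          f"slow/fast {m['assemblage_counts']['slow']}/"
          f"{m['assemblage_counts']['fast']}")
    print("\nper-level signal summary (n_p_lt: resources with RT p < 0.05):")
    print(result["signal_summary"].round(3).to_string(index=False))
    print("\nClade-structured growth shows many significant resources on "
          "the entire tree; within single clades the signal weakens, "
          "mirroring trait conservation at class/order level.")
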
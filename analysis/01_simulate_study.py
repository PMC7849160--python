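"""Generate the synthetic microcosm study: OTU table, phylogeny, metadata,
functional profiles, and the consortium removal series.

Writes everything under results/data/ as TSV/Newick so the downstream analysis
steps (02-06) run from files, the way the real processed data would be used.
"""

import json
from pathlib import Path

from stabilome.io_model import write_count_table
from stabilome.synth import (
    DilutionScenario,
    FunctionalScenario,
    simulate_consortium,
    simulate_dilution_design,
    simulate_functional_profiles,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = DilutionScenario(seed=SEED)
    counts, tree, meta = simulate_dilution_design(scenario)
    write_count_table(counts, OUT / "otu_counts.tsv")
    tree.write(str(OUT / "tree.nwk"))
    meta.table.to_csv(OUT / "metadata.tsv", sep="\t", index_label="sample")
    (OUT / "scenario_manifest.json").write_text(json.dumps(scenario.manifest(), indent=2))

    functional = simulate_functional_profiles(FunctionalScenario(seed=SEED), meta)
    write_count_table(functional, OUT / "functional_profiles.tsv")

    consortium = simulate_consortium(seed=SEED)
    cons_dir = OUT / "consortium"
    cons_dir.mkdir(exist_ok=True)
    for label, table in consortium.items():
        write_count_table(table, cons_dir / f"{label.replace('-', 'minus_')}.tsv")

    print(f"wrote {len(counts.samples)}-sample design ({len(counts.features)} OTUs), "
          f"{len(functional.features)} functional categories, "
          f"{len(consortium)} consortium conditions -> {OUT}")


if __name__ == "__main__":
    main()
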
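"""Pathway over-representation of the featured species' target genes.

Pools target genes of the volcano's up-, down-, and non-featured species
into three lists, tests each list against every pathway (Fisher's exact
test, greater tail), adjusts with Benjamini-Hochberg across all pathways,
flags at FDR 0.05, and ranks pathways by total overlap across the three
groups. Reports how many planted-enriched pathways were flagged.

Reads results/{data,screen}/, writes results/enrich/
"""

import json
from pathlib import Path

import pandas as pd

from evmir import enrich_pathways, top_overlap_pathways
from evmir import io as eio

DATA = Path("results/data")
OUT = Path("results/enrich")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    db = eio.read_gmt(DATA / "pathways.gmt")
    tmap = eio.read_target_map(DATA / "target_map.tsv")
    stats = pd.read_csv(Path("results/screen/species_stats.tsv"),
                        sep="\t").set_index("probe_id")
    featured = pd.read_csv(Path("results/screen/featured_species.tsv"),
                           sep="\t").set_index("probe_id")

    groups = {
        "up": list(featured.index[featured["direction"] == "up"]),
        "down": list(featured.index[featured["direction"] == "down"]),
        "ns": [p for p in stats.index if p not in set(featured.index)],
    }
    tables = {}
    for g, mirnas in groups.items():
        tables[g] = enrich_pathways(tmap.union_targets(mirnas), db)
        eio.write_stats_tsv(tables[g], OUT / f"enrichment_{g}.tsv", "pathway_id")
        print(f"group {g} ({len(mirnas)} miRNAs): "
              f"{int(tables[g]['significant'].sum())} of {len(db)} pathways "
              f"at FDR 0.05")

    top = top_overlap_pathways(tables, k=10)
    eio.write_stats_tsv(top, OUT / "top_pathways.tsv", "pathway_id")
    print("top pathways by total overlap:",
          ", ".join(top.index[:5]), "...")


if __name__ == "__main__":
    main()
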
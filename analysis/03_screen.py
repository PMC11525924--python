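"""Differential screening of the normalized cohort.

Per-species Mann-Whitney U tests (cancer vs noncancer), significance
counts at p < 0.05 / 0.005 / 0.0005, and the volcano filter
(-log10 p > 3.30, |log2 FC| > 1.00). Reports how many of the planted
species the volcano recovered.

Reads results/{data,normalized}/, writes results/screen/
"""

import json
from pathlib import Path

from evmir import screen_cohort, significance_counts, volcano_filter
from evmir import io as eio

DATA = Path("results/data")
OUT = Path("results/screen")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    norm = eio.read_intensity_tsv(Path("results/normalized/normalized.tsv"),
                                  state="normalized")
    labels = eio.read_metadata_tsv(DATA / "metadata.tsv")
    truth = json.loads((DATA / "ground_truth.json").read_text())
    planted = set(truth["planted_up_ids"]) | set(truth["planted_down_ids"])

    stats = screen_cohort(norm, labels)
    eio.write_stats_tsv(stats, OUT / "species_stats.tsv", "probe_id")
    counts = significance_counts(stats)
    for t, c in counts.items():
        print(f"species with p < {t}: {c}")

    featured = volcano_filter(stats)
    eio.write_stats_tsv(featured, OUT / "featured_species.tsv", "probe_id")
    n_up = int((featured["direction"] == "up").sum())
    n_down = int((featured["direction"] == "down").sum())
    hit = len(set(featured.index) & planted)
    print(f"volcano-featured species: {len(featured)} ({n_up} up, {n_down} down)")
    print(f"planted species recovered: {hit}/{len(planted)}; "
          f"unplanted among featured: {len(featured) - hit}")


if __name__ == "__main__":
    main()
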
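"""Reference-table style summaries of both assemblages.

Computes min/max/mean of length, width, ER and hilum angle plus
character frequencies at the 100% sample and the longest-20% stratum,
and writes JSON + a human-readable table per taxon.
"""

from pathlib import Path

from starchmorph import read_granule_csv, summarize_assemblage

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for stem in ("alata", "bulbifera"):
        records = read_granule_csv(RESULTS / f"{stem}_granules.csv")
        summary = summarize_assemblage(records)
        summary.to_json(RESULTS / f"{stem}_summary.json")
        text = summary.to_text()
        (RESULTS / f"{stem}_summary.txt").write_text(text + "\n")
        print(text)
        print()


if __name__ == "__main__":
    main()
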
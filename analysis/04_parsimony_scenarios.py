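#!/usr/bin/env python
"""Map the binary RLSI character on the six phylogenetic hypotheses.

Enumerates every most-parsimonious reconstruction on each packaged
topology with the ape outgroup fixed high, classifying changes as
independent gains of the human-like (low) state vs reversals to the
ape-like (high) state.
"""

from pathlib import Path

from limbjoints import io
from limbjoints.parsimony import (
    CharacterAssignment,
    enumerate_mprs,
    parse_newick,
    scenario_report,
)

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    chars = CharacterAssignment(io.load_character_states())
    results = []
    for label, path in sorted(io.packaged_tree_paths().items()):
        tree = parse_newick(path.read_text(), label=label)
        results.append(enumerate_mprs(tree, chars, root_prior="high"))
    report = scenario_report(results)
    io.write_json(report["topologies"], OUT / "parsimony_report.json")
    (OUT / "parsimony_report.md").write_text(report["markdown"] + "\n")
    print(report["markdown"])
    single = [r["topology"] for r in report["topologies"]
              if r["single_origin_no_reversal"]]
    print(f"\nOnly topology {single} lets the human-like proportions arise "
          "once with no reversals — and it requires A. afarensis to be "
          "sister to later Homo, a relationship no cladistic analysis has "
          "recovered. On every realistic tree the A. afarensis / later "
          "Homo similarity is homoplasy (or must be bought with reversals).")
    print(f"wrote {OUT/'parsimony_report.json'}")


if __name__ == "__main__":
    main()
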
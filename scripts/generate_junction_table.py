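"""Generate the default local-interpretation table for degree-3 junctions.

A junction has three attachment slots.  Each local pattern assigns the
slots to one of:

* all three terminating (three separate mitochondria abut at the site),
* one pass-through pair with the third slot terminating,
* one pass-through pair with the third slot abutting but unconnected
  (kept as a distinct pattern: it describes a different physical scene
  even though it resolves the paths identically),
* a true three-way junction fusing all slots into one branched organelle.

Every pattern covers each slot exactly once and receives equal
probability.  Run from the repository root:

    python scripts/generate_junction_table.py
"""

import itertools
import json
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "mitonet" / "data" / "junction_patterns.json"


def degree3_patterns():
    slots = (0, 1, 2)
    patterns = [
        {"label": "terminate_all", "links": [], "terminated": list(slots)},
    ]
    for a, b in itertools.combinations(slots, 2):
        (c,) = [s for s in slots if s not in (a, b)]
        patterns.append(
            {"label": f"pass_{a}{b}_terminate_{c}", "links": [[a, b]], "terminated": [c]}
        )
    for a, b in itertools.combinations(slots, 2):
        (c,) = [s for s in slots if s not in (a, b)]
        patterns.append({"label": f"pass_{a}{b}_abut_{c}", "links": [[a, b]], "terminated": [c]})
    patterns.append(
        {"label": "fuse_all", "links": [[0, 1], [0, 2], [1, 2]], "terminated": []}
    )
    # sanity: every slot covered exactly once per pattern
    for p in patterns:
        covered = sorted([s for link in p["links"] for s in link] + p["terminated"])
        joined = sorted(set(covered))
        assert joined == list(slots), p
    return patterns


def main():
    table = {"3": degree3_patterns()}
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(table, indent=1) + "\n")
    print(f"wrote {OUT} ({len(table['3'])} degree-3 patterns)")


if __name__ == "__main__":
    main()
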
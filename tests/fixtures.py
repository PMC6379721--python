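"""Programmatically built test fixtures (no binary/data files in the repo).

The caDNAno fixture is a 2-helix, 48-position square-lattice design:

* helix 0 scaffold runs 5'->3' over positions 0..39, helix 1 scaffold
  runs 31..0 (no scaffold crossover, so the two scaffolds are separate
  strands);
* two staples form one double crossover between the helices at positions
  15 and 16 (staple X: helix0 31->16 then helix1 16->31; staple Y:
  helix1 0->15 then helix0 15->0);
* three skips sit at helix 0 positions 34-36 (scaffold-only region) and
  one loop (insertion) of 2 at helix 0 position 38.

Hand counts used by the tests: occupied channel slots = 40 + 32 + 32 +
32 = 136; nucleotides = 136 - 3 skips + 2 insertions = 135; inter-helix
crossovers = 2, paired into 1 double crossover.
"""

from __future__ import annotations

import copy
import json

N_POS = 48
SLOTS = 136
N_SKIPS = 3
N_LOOPED = 2
EXPECTED_NUCLEOTIDES = SLOTS - N_SKIPS + N_LOOPED  # 135
EXPECTED_CROSSOVERS = 2
EXPECTED_DOUBLE_CROSSOVERS = 1


def _empty(n=N_POS):
    return [[-1, -1, -1, -1] for _ in range(n)]


def cadnano_design_dict() -> dict:
    scaf0 = _empty()
    for i in range(40):
        scaf0[i] = [0, i - 1, 0, i + 1]
    scaf0[0] = [-1, -1, 0, 1]
    scaf0[39] = [0, 38, -1, -1]

    scaf1 = _empty()
    for i in range(32):
        scaf1[i] = [1, i + 1, 1, i - 1]
    scaf1[31] = [-1, -1, 1, 30]
    scaf1[0] = [1, 1, -1, -1]

    stap0 = _empty()
    stap1 = _empty()
    # staple X: helix0 31 -> 16, cross, helix1 16 -> 31
    stap0[31] = [-1, -1, 0, 30]
    for i in range(17, 31):
        stap0[i] = [0, i + 1, 0, i - 1]
    stap0[16] = [0, 17, 1, 16]
    stap1[16] = [0, 16, 1, 17]
    for i in range(17, 31):
        stap1[i] = [1, i - 1, 1, i + 1]
    stap1[31] = [1, 30, -1, -1]
    # staple Y: helix1 0 -> 15, cross, helix0 15 -> 0
    stap1[0] = [-1, -1, 1, 1]
    for i in range(1, 15):
        stap1[i] = [1, i - 1, 1, i + 1]
    stap1[15] = [1, 14, 0, 15]
    stap0[15] = [1, 15, 0, 14]
    for i in range(1, 15):
        stap0[i] = [0, i + 1, 0, i - 1]
    stap0[0] = [0, 1, -1, -1]

    skip0 = [0] * N_POS
    for i in (34, 35, 36):
        skip0[i] = -1
    loop0 = [0] * N_POS
    loop0[38] = 2

    return {
        "name": "two-helix-fixture",
        "vstrands": [
            {
                "num": 0, "row": 0, "col": 0,
                "scaf": scaf0, "stap": stap0, "skip": skip0, "loop": loop0,
            },
            {
                "num": 1, "row": 0, "col": 1,
                "scaf": scaf1, "stap": stap1,
                "skip": [0] * N_POS, "loop": [0] * N_POS,
            },
        ],
    }


def write_cadnano_fixture(path) -> str:
    doc = cadnano_design_dict()
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return str(path)


def cadnano_design_with_dangling(path) -> str:
    doc = cadnano_design_dict()
    doc = copy.deepcopy(doc)
    doc["vstrands"][0]["scaf"][5] = [0, 4, 7, 99]  # helix 7 does not exist
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return str(path)
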
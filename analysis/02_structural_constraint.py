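"""Threshold each subject's tractography value maps at 15% of their
maximum and form the per-seed group consensus of structurally connected
cortical regions — the candidate node sets for network identification.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS, ensure_dirs, get_cohort

import pandas as pd

import symnetmap as sn


def main():
    ensure_dirs()
    cohort = get_cohort()
    frames = []
    for seed, maps in cohort.structural.items():
        table = sn.consensus_nodes(maps, fraction=0.15, consensus=0.5)
        frames.append(table.to_frame())
        print(f"seed {seed}: consensus-connected regions "
              f"{table.connected_regions}")
    out = pd.concat(frames)
    out.to_csv(RESULTS / "wm_connections.csv")
    print(f"wrote {RESULTS / 'wm_connections.csv'}")


if __name__ == "__main__":
    main()
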
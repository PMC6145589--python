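"""Generate the matched synthetic cohort and write it to disk.

Creates 13 mycelium-like and 9 vasculature-like planar networks whose node
counts and alpha-index targets copy the published size table, and writes the
node/edge CSV pair for each under scratch/cohort/networks/ (a few megabytes
of regenerable data, hence outside results/).  Anyone wanting to inspect the
synthetic stand-ins can reload them with planarnets.load_network.
"""

import argparse
from pathlib import Path

from planarnets.network import write_network
from planarnets.pipeline import matched_cohort
from planarnets.topology import alpha_index, mean_degree

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort" / "networks"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    for net, group in matched_cohort(seed=args.seed):
        stem = net.name.replace(" ", "_")
        write_network(net, OUT, stem=stem)
        print(
            f"{net.name:<22} {group:<12} N={net.n_nodes:<5} M={net.n_edges:<5} "
            f"<k>={mean_degree(net):.2f} alpha={alpha_index(net):.3f}"
        )
    print(f"wrote cohort to {OUT}")


if __name__ == "__main__":
    main()
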
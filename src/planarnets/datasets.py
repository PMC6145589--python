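"""Published node/edge counts for the 22 empirical distribution networks.

Thirteen mycelial networks (four species/growth conditions: Phallus
impudicus, two Phanerochaete velutina sets, Resinicium bicolor) and nine
rodent pial vasculature networks (four rats, five mice) from the study this
package reanalyses.  Only N and M are public; coordinates are not, which is
why the synthetic generators exist.  These counts are sufficient for the
purely size/density-based group statistics (mean degree 2M/N, alpha index).
"""

from __future__ import annotations

import pandas as pd

FUNGI = "fungi"
VASCULATURE = "vasculature"

#: (name, group, n_nodes, n_edges)
PUBLISHED_COUNTS: list[tuple[str, str, int, int]] = [
    ("P.I. 1", FUNGI, 1357, 1858),
    ("P.I. 2", FUNGI, 543, 725),
    ("P.I. 3", FUNGI, 1029, 1317),
    ("P.I. 4", FUNGI, 1519, 2057),
    ("P.V.1 1", FUNGI, 1212, 1564),
    ("P.V.1 2", FUNGI, 1384, 1851),
    ("P.V.1 3", FUNGI, 1209, 1527),
    ("P.V.2 1", FUNGI, 986, 1351),
    ("P.V.2 2", FUNGI, 551, 627),
    ("P.V.2 3", FUNGI, 553, 670),
    ("P.V.2 4", FUNGI, 948, 1088),
    ("P.V.2 5", FUNGI, 1204, 1468),
    ("R.B.", FUNGI, 602, 850),
    ("Rat 1", VASCULATURE, 1712, 1823),
    ("Rat 2", VASCULATURE, 2043, 2168),
    ("Rat 3", VASCULATURE, 2158, 2296),
    ("Rat 4", VASCULATURE, 2650, 2775),
    ("Mouse 1", VASCULATURE, 826, 855),
    ("Mouse 2", VASCULATURE, 1449, 1481),
    ("Mouse 3", VASCULATURE, 672, 700),
    ("Mouse 4", VASCULATURE, 967, 994),
    ("Mouse 5", VASCULATURE, 947, 973),
]


def published_counts() -> pd.DataFrame:
    """The published size table with derived mean degree and alpha index."""
    df = pd.DataFrame(PUBLISHED_COUNTS, columns=["name", "group", "n_nodes", "n_edges"])
    df["mean_degree"] = 2 * df.n_edges / df.n_nodes
    df["alpha"] = (df.n_edges - df.n_nodes + 1) / (2 * df.n_nodes - 5)
    return df
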
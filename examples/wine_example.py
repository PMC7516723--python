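#!/usr/bin/env python
"""Optional example: CLDIC subset selection on the UCI Wine data.

Requires a user-supplied copy of the UCI Wine table (178 rows; column 1 =
cultivar 1/2/3, then 13 chemical measurements).  Only the first four
explanatory variables are used: Alcohol, Malic acid, Ash, Alkalinity.
Not part of the test suite (the data are an external download):

    python examples/wine_example.py wine.data
"""

import sys

import numpy as np
import pandas as pd

from cldic.criterion import cldic
from cldic.estimation import cmdpde_fit
from cldic.iris import composite_mixture, composite_models, fit_class_conditional
from cldic.models import DataSample, build_qmc_nodes
from cldic.quadrature import IntegralPlan

ALPHAS = (0.0, 0.2, 0.3, 0.4, 0.5, 0.8)
CLASS_NAMES = {1: "BO", 2: "GR", 3: "BA"}  # Barolo, Grignolino, Barbera


def build_wine_subsets(X, labels):
    """20 first rows per cultivar; contaminated variants add 5 rows of one
    other cultivar (n=25) or 3 of each other cultivar (n=26)."""
    rows = {tag: X[labels == tag][:20] for tag in ("BO", "GR", "BA")}
    subs = {tag: rows[tag] for tag in rows}
    for base, extra in (("BO", "GR"), ("BO", "BA"), ("GR", "BO"),
                        ("GR", "BA"), ("BA", "BO"), ("BA", "GR")):
        subs[f"{base}({extra})"] = np.vstack([rows[base],
                                              X[labels == extra][:5]])
    subs["BA(BO+GR)"] = np.vstack([rows["BA"], X[labels == "BO"][:3],
                                   X[labels == "GR"][:3]])
    return subs


def main(path):
    raw = pd.read_csv(path, header=None)
    labels = np.array([CLASS_NAMES[int(v)] for v in raw.iloc[:, 0]])
    X = raw.iloc[:, 1:5].to_numpy(dtype=float)
    plan = IntegralPlan()
    ccm = fit_class_conditional(X, labels)
    cand = composite_models(ccm)
    mix = composite_mixture(ccm)
    nodes = build_qmc_nodes(mix, plan)
    subs = build_wine_subsets(X, labels)
    table = {}
    for a in ALPHAS:
        theta = cmdpde_fit(mix, X, a, plan, nodes=nodes).theta
        table[a] = {nm: min((cldic(m, s, a, theta_hat=theta, plan=plan,
                                   name=cn) for cn, m in cand.items()),
                            key=lambda r: r.cldic).name
                    for nm, s in subs.items()}
    print(pd.DataFrame(table).T.to_string())


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
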
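#!/usr/bin/env python
"""Regenerate the bundled Dixon k-coefficient table (data/dixon_k.tsv).

For each terminal response pattern (O = no withdrawal -> next stimulus one
step up, X = withdrawal -> one step down), the stimulus levels relative to
the final trial are reconstructed in units of the log step, and k is the
maximum-likelihood location of a normal-ogive psychometric function whose
spread equals the step size.  The 50% threshold estimate is then
10**(log10(F_final) + k*delta).  This is the construction behind Dixon's
published staircase coefficients; the classic anchors k(OX) = -0.5 and
k(XO) = +0.5 fall out exactly, and mirrored patterns have opposite signs.

Usage: python scripts/make_dixon_k_table.py  (run from the repository root)
"""

import itertools
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

OUT = Path(__file__).resolve().parents[1] / "src" / "isobolo" / "data" / "dixon_k.tsv"


def levels_for(pattern: str) -> np.ndarray:
    lv = [0.0] * len(pattern)
    for i in range(len(pattern) - 2, -1, -1):
        lv[i] = lv[i + 1] + 1.0 if pattern[i] == "X" else lv[i + 1] - 1.0
    return np.array(lv)


def k_of(pattern: str) -> float:
    lv = levels_for(pattern)
    resp = np.array([ch == "X" for ch in pattern])

    def nll(mu: float) -> float:
        z = lv - mu
        return -(norm.logcdf(z[resp]).sum() + norm.logsf(z[~resp]).sum())

    res = minimize_scalar(nll, bounds=(-8, 8), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def main() -> None:
    rows = []
    for n in range(2, 9):
        for bits in itertools.product("OX", repeat=n):
            pat = "".join(bits)
            if len(set(pat)) < 2:
                continue  # uniform patterns are censored, not tabulated
            rows.append((pat, k_of(pat)))
    with OUT.open("w") as fh:
        fh.write("# Dixon up-down k coefficients, keyed by terminal response pattern.\n")
        fh.write("# O = no withdrawal (next stimulus one step up), X = withdrawal (one step down).\n")
        fh.write("# k is the maximum-likelihood location (in log-step units, relative to the\n")
        fh.write("# final stimulus) of a normal-ogive psychometric function with sigma equal\n")
        fh.write("# to the step size -- the construction behind Dixon's (1980) published\n")
        fh.write("# staircase table; 50%% threshold = 10^(log10(F_final) + k*delta).\n")
        fh.write("# Patterns of length 2-8 containing at least one O and one X.  v1\n")
        fh.write("pattern\tk\n")
        for pat, k in rows:
            fh.write(f"{pat}\t{k:.4f}\n")
    print(f"wrote {len(rows)} patterns -> {OUT}")


if __name__ == "__main__":
    main()
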
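#!/usr/bin/env python
"""FLIM-FRET analysis on simulated TCSPC acquisitions.

Simulates donor-only and donor+acceptor decays at the study lifetimes
(3.62 ns unquenched; 3.04 ns basal; 2.32 ns after 1 M shock), fits them by
Poisson maximum likelihood, converts lifetimes to FRET efficiencies
against the fitted unquenched donor, computes phasor coordinates, and the
fractional lifetime change of the shock.

Writes: results/flim_fits.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from idrfret import flim, synth

CONDITIONS = {
    "donor_only": 3.62,
    "basal": 3.04,
    "shock_1M": 2.32,
}


def main(seed: int, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    fits = {}
    for i, (name, tau) in enumerate(CONDITIONS.items()):
        decay = synth.gen_decay(synth.DecayTruth(
            lifetimes=[tau], total_photons=500_000, seed=seed * 10 + i))
        fit = flim.fit_monoexp(decay)
        phasor = flim.phasor_transform(decay)
        fits[name] = fit
        rows.append({
            "condition": name, "tau_true_ns": tau, "tau_fit_ns": fit.tau,
            "tau_stderr_ns": fit.tau_stderr, "reduced_chi2": fit.reduced_chi2,
            "phasor_g": phasor.g, "phasor_s": phasor.s,
        })
    tau_d = fits["donor_only"].tau
    for row in rows:
        eff = flim.fret_efficiency(row["tau_fit_ns"], tau_d)
        row["fret_efficiency_pct"] = 100 * eff.efficiency
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "flim_fits.csv", index=False)
    print(df.round(4).to_string(index=False))

    dl = flim.delta_lifetime(fits["basal"].tau, fits["shock_1M"].tau)
    print(f"\ndelta-lifetime basal -> 1 M shock: {dl:+.4f} "
          f"({100 * dl:+.1f}% of the initial lifetime)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out_dir)
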
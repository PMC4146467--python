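"""Arrow matrix: direction of change of calcium metrics under each scenario.

Consumes ``results/traces.csv`` and condenses every non-wild-type scenario
into up/down/= arrows for mean, amplitude, peak calcium and Fourier mode
diversity, relative to the wild type.

Outputs
-------
results/arrow_table.csv
results/arrow_table.txt
"""

import argparse
from pathlib import Path

import pandas as pd

from saspnet.ensemble import EnsembleSeries, summarize
from saspnet.perturbations import scenario_suite
from saspnet.reporting import ScenarioResult, build_arrow_table
from saspnet.spectral import power_spectrum


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results", type=Path)
    ap.add_argument("--window", type=int, default=50)
    ap.add_argument("--rel-tol", type=float, default=0.01)
    args = ap.parse_args()
    traces = pd.read_csv(args.out_dir / "traces.csv")

    specs = {s.label: s for s in scenario_suite()}
    results = {}
    for label, grp in traces.groupby("scenario", sort=False):
        x = grp.sort_values("t")["ca_mean"].to_numpy()
        series = EnsembleSeries(
            values=x,
            node="Ca",
            n_ic=-1,
            seed=None,
            transient_discarded=0,
            spec=specs[label],
        )
        results[label] = ScenarioResult(
            spec=specs[label],
            series=series,
            stats=summarize(series, window=args.window),
            spectrum=power_spectrum(x, n_steps=min(1000, x.size)),
        )
    table = build_arrow_table(results, rel_tol=args.rel_tol)
    table.frame.to_csv(args.out_dir / "arrow_table.csv")
    (args.out_dir / "arrow_table.txt").write_text(table.to_text() + "\n")
    print(table.to_text())


if __name__ == "__main__":
    main()
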
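"""Assemble the toy phase diagram from the sweep outputs.

Reads results/eos.csv and results/order_series.csv written by
05_eos_sweep.py (re-running it if missing), locates the positional and
rotational Lindemann crossings, interpolates each to a concentration,
spacing and EoS pressure, and writes results/phase_report.json.
"""

import json
import runpy
from pathlib import Path

import numpy as np
import pandas as pd

from dnarray.eos import EoSTable, assemble_phase_diagram
from dnarray.order import OrderSeriesPoint

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    if not (OUT / "eos.csv").exists() or not (OUT / "order_series.csv").exists():
        runpy.run_path(str(Path(__file__).with_name("05_eos_sweep.py")),
                       run_name="__main__")
    eos = pd.read_csv(OUT / "eos.csv")
    series_df = pd.read_csv(OUT / "order_series.csv")
    table = EoSTable(spacing=eos["spacing"].to_numpy(),
                     concentration=eos["concentration"].to_numpy(),
                     pressure=eos["pressure"].to_numpy(),
                     pressure_sd=eos["pressure_sd"].to_numpy())
    series = [OrderSeriesPoint(**row) for row in series_df.to_dict("records")]
    report = assemble_phase_diagram(series, table, threshold=0.1,
                                    lattice_kind="hex", b_over_a=np.sqrt(3.0))

    doc = {
        "threshold": report.threshold,
        "positional_crossing": None if report.positional is None else vars(report.positional),
        "rotational_crossing": None if report.rotational is None else vars(report.rotational),
        "bands": report.bands.to_dict(orient="records"),
    }
    (OUT / "phase_report.json").write_text(json.dumps(doc, indent=2))
    for name in ("positional", "rotational"):
        x = getattr(report, name)
        if x is None:
            print(f"{name} Lindemann crossing: open boundary (no crossing)")
        else:
            print(f"{name} Lindemann crossing: {x.concentration:.0f} mg/ml "
                  f"(d = {x.spacing:.2f} nm, Pi = {x.pressure:.2f} pN/nm^2)")
    print(report.bands.to_string(index=False))


if __name__ == "__main__":
    main()
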
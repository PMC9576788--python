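#!/usr/bin/env python
"""Solve the baseline confined-cell steady state and tabulate it.

Baseline conditions: SWELL1 (passive Cl-) enriched 4x at the cell rear,
NHE mildly enriched at the front, actin polymerization on.  Writes the
nodal profile table and a scalar summary under results/.
"""

import json
from pathlib import Path

from osmoengine.params import default_parameters
from osmoengine.solver import SolverOptions, solve_steady

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    params = default_parameters()
    state = solve_steady(params, SolverOptions(grid_size=64))
    OUT.mkdir(exist_ok=True)

    table = state.profiles.to_frame(params)
    with open(OUT / "baseline_profiles.tsv", "w") as fh:
        fh.write("# baseline steady state: x um, p Pa, velocities um/s, "
                 "concentrations mM, phi mV\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    summary = {**state.summary(), "diagnostics": state.diagnostics}
    (OUT / "baseline_summary.json").write_text(
        json.dumps(summary, indent=2, default=str))

    s = state.summary()
    print(f"baseline steady state (N=64): v0 = {state.v0:.4g} um/s "
          f"({state.v0 * 3600:.3g} um/h)")
    print(f"  water influx at the front {s['front.j_water']:.3g} um/s, "
          f"equal efflux at the rear — the osmotic engine loop")
    print(f"  membrane potential {s['front.v_m']:.1f} mV, "
          f"intracellular pH {s['front.ph']:.2f}")
    print(f"  conservation: electroneutrality {state.diagnostics['electroneutrality']:.1e}, "
          f"actin {state.diagnostics['actin_conservation']:.1e} (relative)")
    print(f"wrote {OUT / 'baseline_profiles.tsv'} and baseline_summary.json")


if __name__ == "__main__":
    main()
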
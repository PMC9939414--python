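"""Validate the flow solver against its four closed-form channel benchmarks:
plane Poiseuille (centerline + wall shear), Womersley oscillatory flow,
the Darcy porous limit, and the regularised Casson channel profile.

Writes results/benchmarks.csv with measured/analytic values and relative
errors, and prints a pass/fail line per check.
"""

from pathlib import Path

import pandas as pd

from coilflow.benchmarks import run_benchmarks

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

TOL = {
    ("poiseuille", "centerline"): 0.02,
    ("poiseuille", "wall_shear"): 0.03,
    ("womersley", "centerline_amplitude"): 0.05,
    ("darcy", "bulk_velocity"): 0.05,
    ("casson-channel", "centerline"): 0.05,
    ("casson-channel", "bulk"): 0.05,
}


def main():
    rows = []
    for bench, res in run_benchmarks("all").items():
        for key, val in res.items():
            if not (isinstance(val, dict) and "rel_err" in val):
                continue
            tol = TOL.get((bench, key))
            ok = tol is None or val["rel_err"] <= tol
            rows.append({
                "benchmark": bench, "quantity": key,
                "measured": val["measured"], "analytic": val["analytic"],
                "rel_err": val["rel_err"], "tolerance": tol,
                "status": "pass" if ok else "FAIL",
            })
            print(f"{bench:15s} {key:22s} measured={val['measured']:.6g} "
                  f"analytic={val['analytic']:.6g} rel_err={val['rel_err']:.3%} "
                  f"{'pass' if ok else 'FAIL'}")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "benchmarks.csv", index=False)
    print(f"wrote {OUT/'benchmarks.csv'}")
    if (table.status == "FAIL").any():
        raise SystemExit(1)


if __name__ == "__main__":
    main()
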
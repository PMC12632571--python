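"""Model the growth of word-rate entrainment over learning.

Fits the mixed model smoothed_pseudovalue ~ epoch_number x group +
(1 | subject) on the first half of exposure, at the word frequency, and
reports per-group marginal slopes: the control-like group should show a
positive learning slope, the Fragile-X-like group none.  Reads the
pseudovalue table written by 02_cohort_entrainment.py.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from entrainkit.timecourse import fit_timecourse  # noqa: E402

OUT = ROOT / "results" / "analysis"


def main() -> None:
    warnings.filterwarnings("ignore")
    pv = pd.read_csv(OUT / "pseudovalues.csv")
    out = {}
    for freq in ("word", "syllable"):
        fit = fit_timecourse(pv[pv["frequency"] == freq],
                             first_half_only=True)
        out[freq] = {
            "method": fit.method,
            "params": fit.params,
            "pvalues": fit.pvalues,
            "slopes": fit.slopes,
            "n_obs": fit.n_obs,
        }
        print(f"{freq}: model = {fit.method}, n_obs = {fit.n_obs}")
        for grp, s in fit.slopes.items():
            print(f"  {grp} marginal slope {s['estimate']:+.4f} "
                  f"(SE {s['se']:.4f}), t = {s['t']:.2f}, p = {s['p']:.4g}")
    (OUT / "timecourse_fit.json").write_text(
        json.dumps(out, indent=2, default=float)
    )
    print(f"wrote {OUT / 'timecourse_fit.json'}")


if __name__ == "__main__":
    main()
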
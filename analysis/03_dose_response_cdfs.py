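"""Plot the cumulative distributions of vertex p-values per contrast.

Against the y = x null line, a contrast with a real effect bows upward; the
deviation at p <= 0.05 grows with the implanted dose difference, giving a
dose-response analog at map level.  Requires 02_run_pipeline.py to have run.
"""

from pathlib import Path

import pandas as pd

from hippomorph import stats as st

ROOT = Path(__file__).resolve().parent.parent / "results"
CONTRASTS = ROOT.parent / "scratch" / "pipeline_run" / "contrasts"

curves = {}
for f in sorted(CONTRASTS.glob("*_cdf.csv")):
    name = f.name.replace("_cdf.csv", "")
    df = pd.read_csv(f)
    curves[name] = st.CdfCurve(
        p_sorted=df["p"].to_numpy(), cum_fraction=df["cdf"].to_numpy()
    )

st.plot_cdfs(curves, ROOT / "cdf_all_contrasts.png", max_abscissa=1.0)
st.plot_cdfs(curves, ROOT / "cdf_zoom.png", max_abscissa=0.05)

rows = [
    {"contrast": name, "cdf_at_005": c.value_at(0.05),
     "deviation_from_null": c.value_at(0.05) - 0.05}
    for name, c in curves.items()
]
table = pd.DataFrame(rows).sort_values("deviation_from_null", ascending=False)
table.to_csv(ROOT / "cdf_deviation_table.csv", index=False)
print(table.to_string(index=False))
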
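"""Cross-validation against an independent ANOVA implementation.

Runs base R's ``aov`` with ``Error(subject/(A*B*...))`` strata through
``Rscript`` on a long-format table and returns the per-effect df/SS/F/p.
Used by the test suite and the acceptance script to check the from-scratch
decomposition in :mod:`cylgrip.anova` against software this package does
not share a line of code with.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import pandas as pd

_R_TEMPLATE = """
d <- read.csv("{data_csv}")
d${subject} <- factor(d${subject})
{factorize}
s <- summary(aov({dv} ~ {formula} + Error({subject}/({formula})), data = d))
rows <- do.call(rbind, lapply(s, function(st) {{
  df <- as.data.frame(st[[1]])
  names(df) <- c("df", "ss", "ms", "F", "p_value")[seq_along(names(df))]
  df$source <- trimws(rownames(df))
  df
}}))
write.csv(rows, "{out_csv}", row.names = FALSE)
"""


def reference_rm_anova(data: pd.DataFrame, dv: str, within: list[str],
                       subject: str) -> pd.DataFrame:
    """Independent RM-ANOVA table from R ``aov``.

    Returns a DataFrame with columns ``source, df, ss, ms, F, p_value``
    containing the effect rows (error strata rows are dropped); ``source``
    uses the same ``factor1:factor2`` naming as
    :func:`cylgrip.anova.rm_anova`.
    """
    with tempfile.TemporaryDirectory() as td:
        data_csv = Path(td) / "data.csv"
        out_csv = Path(td) / "out.csv"
        data.to_csv(data_csv, index=False)
        script = _R_TEMPLATE.format(
            data_csv=data_csv.as_posix(), out_csv=out_csv.as_posix(),
            dv=dv, subject=subject,
            formula="*".join(within),
            factorize="\n".join(f"d${f} <- factor(d${f})" for f in within),
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"Rscript failed: {proc.stderr[-2000:]}")
        ref = pd.read_csv(out_csv)
    ref = ref[ref["source"] != "Residuals"].reset_index(drop=True)
    return ref[["source", "df", "ss", "ms", "F", "p_value"]]
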
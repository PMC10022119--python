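"""File-based pipeline: write CSVs, read them back, check, and summarize.

Mirrors what the `vaxqc` command line does: synthetic inputs are written
as the three CSV tables, read back through the validating readers, and
assessed; the flag panel is then fed to the trend model with a spline in
year for a plottable curve.
"""

import tempfile
from pathlib import Path

from vaxqc import (
    Dataset,
    GeneratorConfig,
    ModelSpec,
    assess_dataset,
    fit_flag_model,
    flag_table,
    generate_dataset,
    spline_trend,
    write_dataset,
)

with tempfile.TemporaryDirectory() as tmp:
    config = GeneratorConfig(seed=3, n_countries=30)
    dataset, _ = generate_dataset(config)
    paths = write_dataset(dataset, tmp)
    print("wrote:", ", ".join(Path(p).name for p in paths.values()))

    reread = Dataset.read(paths["coverage"], paths["reference"], paths["attributes"])
    reports = assess_dataset(reread)
    panel = flag_table(reports)
    print(f"reassessed from CSV: {len(panel)} reports, "
          f"{panel.flagged.mean() * 100:.1f}% flagged")

    fit = fit_flag_model(panel, ModelSpec(year="spline", spline_df=5))
    curve = spline_trend(fit)
    print("\nspline trend of flag probability (typical country):")
    for _, row in curve[curve.year % 5 == 0].iterrows():
        print(f"  {row.year}: {row.probability:.3f} "
              f"({row.ci_low:.3f}-{row.ci_high:.3f})")
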
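"""Marker quality control on the simulated panel.

Applies the chip-panel filters — MAF <= 0.05 removed (inclusive boundary),
Hardy-Weinberg screening, call-rate filtering — then mean-imputes the
surviving panel, and reports how many markers each rule removed.
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
settings = importlib.import_module("00_settings")

from gsnue import io as gio
from gsnue.qc import apply_qc


def main() -> None:
    out = settings.RESULTS
    G = gio.read_genotypes(out / "genotypes.tsv")

    Gq, report = apply_qc(G, maf_threshold=0.05, hwe_alpha=1e-4, min_call_rate=0.95)

    gio.write_genotypes_tsv(Gq, out / "genotypes_qc.tsv")
    report.per_marker.to_csv(out / "qc_per_marker.tsv", sep="\t", index=False,
                             float_format="%.8g")
    with open(out / "qc_report.json", "w") as fh:
        json.dump(
            {k: getattr(report, k) for k in (
                "n_markers_in", "n_removed_maf", "n_removed_hwe",
                "n_removed_callrate", "n_markers_out")},
            fh, indent=1, sort_keys=True,
        )

    print(f"markers in: {report.n_markers_in}")
    print(f"removed by MAF <= 0.05: {report.n_removed_maf}")
    print(f"removed by HWE p < 1e-4: {report.n_removed_hwe}")
    print(f"removed by call rate < 0.95: {report.n_removed_callrate}")
    print(f"polymorphic panel retained: {report.n_markers_out} markers")


if __name__ == "__main__":
    main()
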
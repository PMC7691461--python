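#!/usr/bin/env python
"""Summary report and figures from the accumulated stage outputs.

Writes results/sim/summary.txt plus per-window figure panels, and echoes the
summary to stdout.  Run after the earlier numbered stages.
"""

from pathlib import Path

from aspenscan import pipeline

SIM = str(Path(__file__).resolve().parents[1] / "results" / "sim")


def main() -> None:
    res = pipeline.run_report(SIM)
    print(open(res["summary"]).read())
    for f in res["figures"]:
        print(f"figure: {f}")


if __name__ == "__main__":
    main()
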
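#!/usr/bin/env python
"""Assemble the Markdown report from the saved diagnostic artifacts."""

import argparse
from pathlib import Path

from kmsens.pipeline import write_report

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

body = write_report(
    {
        "censoring_report": args.out_dir / "censoring_report.json",
        "flip": args.out_dir / "flip.json",
    },
    args.out_dir / "report.md",
)
print(body)
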
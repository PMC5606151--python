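#!/usr/bin/env python
"""Informal timing of the detection pipeline on synthetic records.

Wall-clock numbers are hardware-dependent and asserted nowhere; this script
only illustrates how processing time scales with record length.

Usage: python scripts/profile_timing.py [--seed N]
"""

from __future__ import annotations

import argparse
import time
from dataclasses import replace

from rpeakdet.synthetic import generate, preset
from rpeakdet.thresholding import detect


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    base = preset("noisy")
    for mult in (1, 2, 4, 8, 16):
        cfg = replace(base, duration_s=base.duration_s * mult, seed=args.seed)
        rec, _ = generate(cfg)
        t0 = time.perf_counter()
        peaks = detect(rec)
        dt = time.perf_counter() - t0
        print(f"{rec.duration_s:7.0f} s ({len(rec):8d} samples): "
              f"{dt:7.3f} s wall, {len(peaks):5d} peaks")


if __name__ == "__main__":
    main()
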
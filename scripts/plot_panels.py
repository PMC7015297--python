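#!/usr/bin/env python
"""Regenerate figure-style panels from CSVs written by the fxpode CLI.

  python scripts/plot_panels.py bed hist.csv -o bed.png          # histogram
  python scripts/plot_panels.py lag lag.csv -o lag.png           # lag series
  python scripts/plot_panels.py ensemble ens.csv -o ens.png      # mean +/- SD band
  python scripts/plot_panels.py sweep sweep.csv -o sweep.png     # errorbars vs key
  python scripts/plot_panels.py trace trace.csv [more.csv] -o tr.png
"""

import argparse

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("kind", choices=["bed", "lag", "ensemble", "sweep", "trace"])
    ap.add_argument("csv", nargs="+")
    ap.add_argument("-o", "--out", required=True)
    args = ap.parse_args()

    fig, ax = plt.subplots(figsize=(6, 4))
    if args.kind == "bed":
        df = pd.read_csv(args.csv[0])
        ax.hist(df["error_lsb"], bins=64)
        ax.set_xlabel("error (LSB)")
        ax.set_ylabel("count")
    elif args.kind == "lag":
        df = pd.read_csv(args.csv[0])
        ax.plot(df["spike"], df["lag_ms"])
        ax.axhline(0, ls=":", c="k")
        ax.set_xlabel("spike #")
        ax.set_ylabel("lag (ms)")
    elif args.kind == "ensemble":
        df = pd.read_csv(args.csv[0])
        ax.plot(df["spike"], df["mean_lag_ms"])
        ax.fill_between(df["spike"], df["mean_lag_ms"] - df["sd_ms"],
                        df["mean_lag_ms"] + df["sd_ms"], alpha=0.3)
        ax.axhline(0, ls=":", c="k")
        ax.set_xlabel("spike #")
        ax.set_ylabel("lag (ms)")
    elif args.kind == "sweep":
        df = pd.read_csv(args.csv[0])
        xcol = df.columns[0]
        ax.errorbar(range(len(df)), df["mean_lag_ms"], yerr=df["sd_ms"],
                    fmt="o-", capsize=3)
        ax.set_xticks(range(len(df)), [str(x) for x in df[xcol]])
        ax.axhline(0, ls=":", c="k")
        ax.set_xlabel(xcol)
        ax.set_ylabel("lag (ms)")
    else:  # trace
        for path in args.csv:
            df = pd.read_csv(path)
            ax.plot(df["t_ms"], df["v"], label=path)
        ax.set_xlabel("t (ms)")
        ax.set_ylabel("v (mV)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
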
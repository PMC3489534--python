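"""Plot an experiment report written by `lcms-prep experiment`.

Usage:
    python examples/plot_experiment.py coverage.json coverage.png
    python examples/plot_experiment.py ordering.json trends.png

Experiments emit only numbers (TSV/JSON); this thin consumer turns a report
into a figure.  Requires matplotlib (installed via the ``plot`` extra).
"""

import json
import sys


def main(report_path: str, out_path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    payload = json.loads(open(report_path).read())
    name = payload["name"]
    fig, ax = plt.subplots(figsize=(6, 4))
    if name == "coverage":
        rows = payload["table"]
        x = [r["censored_target"] for r in rows]
        y = [100 * r["coverage"] for r in rows]
        ax.plot(x, y, "o-")
        ax.axhline(95, ls="--", c="grey", lw=1)
        ax.set_xlabel("censored fraction")
        ax.set_ylabel("coverage of nominal 95% CIs (%)")
        ax.set_title(f"strategy: {payload['config']['strategy']}")
    elif name == "ordering":
        vecs = payload["extras"]["trend_vectors"]
        for i, (cond, trends) in enumerate(vecs.items()):
            for t, v in enumerate(trends):
                ax.plot(range(1, len(v) + 1), [x + 2.5 * i for x in v],
                        label=f"{cond} t{t + 1}" if t == 0 else None,
                        alpha=1.0 - 0.3 * t)
        ax.set_xlabel("sample index")
        ax.set_ylabel("eigentrend (offset per condition)")
        ax.legend(fontsize=7)
    elif name == "null_pvalues":
        counts = payload["extras"]["bin_counts"]
        ax.bar(range(len(counts)), counts, width=0.9)
        ax.axhline(sum(counts) / len(counts), ls="--", c="grey", lw=1)
        ax.set_xlabel("p-value bin")
        ax.set_ylabel("count")
        ax.set_title(f"pipeline: {payload['table'][0]['pipeline']}, "
                     f"KS p = {payload['table'][0]['ks_p']:.3g}")
    else:
        raise SystemExit(f"unknown report type {name!r}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    if len(sys.argv) != 3:
        raise SystemExit(__doc__)
    main(sys.argv[1], sys.argv[2])
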
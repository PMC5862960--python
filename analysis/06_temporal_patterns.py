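#!/usr/bin/env python
"""Diel and seasonal detection patterns with mean-valued-null KS tests.

Bins distinct sharks by hour of day (per shallow-recreation site) and by
month (per island), then tests each observed frequency vector against a
flat null holding the mean in every bin.
"""

from pathlib import Path

import pandas as pd

from sharkmove import io as smio
from sharkmove.temporal import bin_distinct_sharks, ks_two_sample

BASE = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    detections = smio.read_detections_csv(BASE / "detections.csv")
    receivers = smio.read_receivers_csv(BASE / "receivers.csv")

    results, bins_out = [], []
    for rx in receivers:
        if rx.use_class != "shallow-recreation":
            continue
        sub = detections[detections["receiver_id"] == rx.receiver_id]
        b = bin_distinct_sharks(sub, "hour", scope=rx.receiver_id)
        d, p, degenerate = ks_two_sample(b)
        results.append({"scope": rx.receiver_id, "resolution": "hour", "D": d, "p": p,
                        "degenerate": degenerate})
        bins_out.append(b.counts.rename(rx.receiver_id))

    for island in sorted({r.island for r in receivers}):
        ids = [r.receiver_id for r in receivers if r.island == island]
        sub = detections[detections["receiver_id"].isin(ids)]
        b = bin_distinct_sharks(sub, "month", scope=island)
        d, p, degenerate = ks_two_sample(b)
        results.append({"scope": f"island-{island}", "resolution": "month", "D": d, "p": p,
                        "degenerate": degenerate})

    table = pd.DataFrame(results)
    table.to_csv(BASE / "temporal_ks.csv", index=False)
    pd.concat(bins_out, axis=1).to_csv(BASE / "diel_bins.csv")
    print(table.round(4).to_string(index=False))
    print(
        "\nnote: the mean-valued null compares integer bin counts against a"
        "\nfractional mean, so even near-flat diel patterns can yield large D"
        "\n(every observed count sits on one side of the mean). The monthly"
        "\ntests reflect the one-month simulated window (all mass in one bin)."
        "\nInterpret D against these constructions, not as a generic"
        "\nuniformity test."
    )


if __name__ == "__main__":
    main()
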
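"""Backward elimination over time-lag windows (lag relevance).

Simulates a recording whose response kernel is confined to ~200-250 ms,
then asks which 50 ms lag windows the TRF cannot afford to lose: for each
window tiling -150..750 ms, the model is refit without it and the drop in
held-out prediction (r_LOSS) is tested against a circular-shift null.
Writes the per-window table under results/lags/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from melodytrf.synth import pink_noise
from melodytrf.trf import backward_eliminate_lags


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results") / "lags")
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()

    fs = 64.0
    rng = np.random.default_rng(args.seed)
    n_tr, T = 10, int(40 * fs)
    kernel = np.zeros(int(0.4 * fs))
    kernel[int(0.2 * fs): int(0.25 * fs) + 1] = 1.0
    feats, resps = [], []
    for _ in range(n_tr):
        x = rng.normal(size=(T, 1))
        y = np.convolve(x[:, 0], kernel)[:T]
        y = y + pink_noise(T, 1, 1.0, rng)[:, 0] * y.std()
        feats.append(x)
        resps.append(y[:, None])

    res = backward_eliminate_lags(feats, resps, fs, n_perm=args.n_perm,
                                  seed=args.seed + 1)
    args.out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({
        "window_start_ms": res.window_starts_ms,
        "window_end_ms": res.window_starts_ms + res.window_ms,
        "r_loss": res.r_loss[:, 0],
        "p_value": res.p_values[:, 0],
        "significant": res.significant[:, 0],
    })
    table.to_csv(args.out / "lag_relevance.csv", index=False,
                 float_format="%.6f")
    sig = table[table.significant]
    (args.out / "summary.json").write_text(json.dumps({
        "r_full_mean": float(res.r_full.mean()),
        "n_significant_windows": int(len(sig)),
        "significant_windows_ms": [
            [float(a), float(b)]
            for a, b in zip(sig.window_start_ms, sig.window_end_ms)
        ],
    }, indent=2))

    print(f"full-model held-out r: {res.r_full.mean():.3f}")
    print("significant lag windows (Bonferroni, circular-shift null):")
    for _, row in sig.iterrows():
        print(f"  {row.window_start_ms:4.0f}..{row.window_end_ms:4.0f} ms  "
              f"r_LOSS = {row.r_loss:.4f}  (p = {row.p_value:.4g})")
    print("the true kernel support (~200-250 ms) should be covered, and "
          "nothing else")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
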
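#!/usr/bin/env python
"""Budget search that produced the shipped architecture.

The published model fixes the skeleton — residual blocks interleaved with
max-pooling, a 4x2x2 convolution to 32 features, global average pooling,
then a 1-D convolutional head 32 -> ... -> 1 — and its total trainable
parameter count (90 124), but not the individual widths.  This script
enumerates admissible widths (three blocks; the second no wider than the
first, per the published description; depth otherwise increasing; a
decreasing 1-D head with an odd kernel) and prints every combination whose
parameter count hits the budget exactly.  The shipped default,
sfe_channels=(16, 8, 40) with tfe_channels=(17, 6) and kernel 7, is one
admissible member of this family.

Usage:
    python scripts/architecture_search.py [--budget 90124]
"""

import argparse


def resblock_params(c_in: int, c_out: int) -> int:
    p = 27 * c_in * c_out + c_out + 27 * c_out * c_out + c_out
    if c_in != c_out:
        p += c_in * c_out + c_out  # 1x1x1 projection
    return p


def total_params(w1: int, w2: int, w3: int, kernel: int, hidden: tuple[int, ...]) -> int:
    p = resblock_params(1, w1) + resblock_params(w1, w2) + resblock_params(w2, w3)
    p += 4 * 2 * 2 * w3 * 32 + 32  # cuboid conv to the 32-feature vector
    chans = (32,) + tuple(hidden) + (1,)
    for a, b in zip(chans, chans[1:]):
        p += kernel * a * b + b
    return p


def search(budget: int):
    for w1 in range(8, 25):
        for w2 in range(4, w1 // 2 + 1):  # second block deliberately narrow
            for w3 in range(32, 65, 8):
                if w3 < w1:
                    continue
                for kernel in (3, 5, 7):
                    for h1 in range(8, 65):
                        rest = budget - total_params(w1, w2, w3, kernel, (h1,))
                        # solve for a second hidden width h2 analytically:
                        # replacing the closing conv (k*h1 + 1 params) with
                        # h1->h2->1 adds k*h1*h2 + h2 + k*h2 + 1 - (k*h1 + 1)
                        denom = kernel * h1 + 1 + kernel
                        numer = rest + kernel * h1
                        if numer > 0 and numer % denom == 0:
                            h2 = numer // denom
                            if 2 <= h2 <= h1:
                                yield (w1, w2, w3, kernel, (h1, h2))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--budget", type=int, default=90_124)
    args = parser.parse_args()
    print(f"configurations with exactly {args.budget} trainable parameters:")
    for w1, w2, w3, kernel, hidden in search(args.budget):
        count = total_params(w1, w2, w3, kernel, hidden)
        assert count == args.budget
        print(
            f"  sfe_channels=({w1}, {w2}, {w3})  tfe_kernel={kernel}  "
            f"tfe_channels={hidden}  -> {count}"
        )


if __name__ == "__main__":
    main()
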
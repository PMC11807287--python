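#!/usr/bin/env bash
# The same single-patient workflow via the command-line interface.
# Each subcommand wraps one library call; artifacts are ordinary files
# (NIfTI phantom, HDF5 system matrix, text counts, JSON estimate).
set -euo pipefail

work=$(mktemp -d)
trap 'rm -rf "$work"' EXIT

mewpdq make-phantom --lesion-diameter 33.75 --out "$work/phantom"
mewpdq build-sysmat --phantom "$work/phantom" --n-angles 24 --out "$work/sysmat.h5"
mewpdq simulate --phantom "$work/phantom" --sysmat "$work/sysmat.h5" \
    --seed 7 --out "$work/counts.txt"
mewpdq estimate --projections "$work/counts.txt" --sysmat "$work/sysmat.h5" \
    --iters 1000 --out "$work/estimate.json"

cat "$work/estimate.json"

# Full desk-scale studies (each writes CSV tables plus a manifest):
#   mewpdq experiment convergence --seed 0 --out-dir results/convergence
#   mewpdq experiment vit         --seed 0 --out-dir results/vit
#   mewpdq experiment lesion_diameter --seed 0 --out-dir results/sweep
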
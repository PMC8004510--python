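#!/usr/bin/env bash
# The same pipeline as the Python examples, via the command-line stages.
# Every stage is deterministic for a fixed --seed: rerunning reproduces the
# output files byte for byte.
set -euo pipefail
out=$(mktemp -d)

# electrode file: a 32-channel synthetic montage (SFP, label x y z per line)
python - "$out" <<'PY'
import sys
import eegstream as es
from eegstream.geometry import write_electrodes_sfp
write_electrodes_sfp(es.fibonacci_montage(32), sys.argv[1] + "/montage.sfp")
PY

eegstream leadfield --electrodes "$out/montage.sfp" --spacing 20 --out "$out/lf.h5"

printf 'adjacency_mm: 60.0\nnoise_cov: identity\n' > "$out/config.yml"

eegstream simulate --leadfield "$out/lf.h5" --mode calibration --duration 60 \
    --seed 0 --out "$out/cal"
eegstream simulate --leadfield "$out/lf.h5" --mode task --trials 10 \
    --seed 0 --out "$out/task"

eegstream calibrate --recording "$out/cal.json" --leadfield "$out/lf.h5" \
    --config "$out/config.yml" --seed 0 --out "$out/filters.h5"

eegstream stream --filters "$out/filters.h5" --input "$out/task.json" \
    --out "$out/stream"

eegstream erd --source-stream "$out/stream" --recording "$out/task.json" \
    --out "$out/erd"

cat "$out/erd/erd_stats.json"
echo "outputs in $out"
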
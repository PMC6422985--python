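#!/usr/bin/env bash
# Download the open-access CTU-UHB intrapartum cardiotocography database
# (552 records with umbilical-artery pH annotations) from PhysioNet.
#
# The library itself never touches the network; run this once, then point
# the CLI / readers at the downloaded directory:
#
#   ./scripts/fetch_ctu_uhb.sh data/ctu-uhb
#   python -c "from ctgrp.io import read_physionet_record as r; print(r('data/ctu-uhb/1001'))"
#
# Requires wget (or substitute curl). ~1 GB on disk.

set -euo pipefail

DEST="${1:-data/ctu-uhb}"
mkdir -p "$DEST"

wget -r -N -c -np -nH --cut-dirs=3 -P "$DEST" \
    https://physionet.org/files/ctu-uhb-ctgdb/1.0.0/

echo "CTU-UHB database downloaded to $DEST"
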
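"""Detect bursts and synchronous network events in a hand-built train.

A burst is a dense spike cluster on one electrode (max-interval rules);
a network spike needs >= min_participants distinct electrodes firing in
the same 25-ms bin; a network burst needs that many electrodes bursting
simultaneously.
"""

import numpy as np

from spikewell import (
    Burst,
    BurstParams,
    NetworkParams,
    detect_bursts,
    detect_network_bursts,
    detect_network_spikes,
)

# one electrode: a 6-spike burst at t=1 s, a stray spike, a burst at t=4 s
train = np.array([1.00, 1.02, 1.04, 1.06, 1.08, 1.10, 2.5, 4.00, 4.03, 4.06, 4.09, 4.12])
bursts = detect_bursts(train, BurstParams(), electrode_id="11")
print("bursts on electrode 11:")
for b in bursts:
    print(f"  [{b.start_s:.2f}, {b.end_s:.2f}] s, {b.n_spikes} spikes,"
          f" duration {b.duration_s * 1000:.0f} ms")
# Both clusters qualify (>= 5 spikes, >= 50 ms, gap 2.9 s > min IBI 0.8 s).

electrodes = [f"{r}{c}" for r in range(1, 9) for c in range(1, 9)]
active = frozenset(electrodes)

# 20 electrodes fire within one 25-ms bin -> one network spike
times = [5.001 + 0.001 * i for i in range(20)]
events = detect_network_spikes(times, electrodes[:20], active, NetworkParams())
print(f"network spikes detected: {len(events)} "
      f"({events[0].n_participants} participants)" if events else "none")

# 16 electrodes each burst over [10, 11] s -> one network burst;
# with only 15 the event is filtered (below 25% of 64 electrodes)
def overlapping_bursts(n):
    return {
        e: [Burst(electrode_id=e, start_s=10.0, end_s=11.0, n_spikes=8)]
        for e in electrodes[:n]
    }

for n in (16, 15):
    nb = detect_network_bursts(overlapping_bursts(n), active, NetworkParams())
    print(f"{n} simultaneously bursting electrodes -> {len(nb)} network burst(s)")
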
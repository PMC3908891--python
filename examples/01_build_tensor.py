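"""Build a snapshot tensor from a timestamped contact edge list.

Writes a tiny SocioPatterns-style contact file, bins the events into
half-open intervals, and prints the tensor and its time-aggregated network.
"""

import tempfile
from pathlib import Path

from tenec import aggregate_time, build_tensor, read_edge_list

CONTACTS = """\
20 alice bob
40 bob carol
60 alice bob
65 alice bob
110 carol dave
115 alice carol
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "contacts.dat"
    path.write_text(CONTACTS)
    net = read_edge_list(path)

print(f"{net.n_nodes} nodes: {net.nodes}")
print(f"{len(net.events)} contact events between t={net.events[0][0]} and t={net.t_max}")

# 60-second intervals -> ceil((115 - 0 + 1) / 60) = 2 snapshots
tensor = build_tensor(net, interval_length=60, t0=0)
print(f"tensor shape {tensor.values.shape} (N x N x S), binary={tensor.is_binary}")
for m in range(tensor.n_intervals):
    links = int(tensor.values[:, :, m].sum() / 2)
    print(f"  snapshot {m}: {links} links")
# alice-bob had contacts at t=20, 60 and 65: two intervals -> aggregated weight 2
agg = aggregate_time(tensor)
i, j = tensor.node_index["alice"], tensor.node_index["bob"]
print(f"aggregated weight alice-bob = {agg.weights[i, j]} "
      "(number of intervals with at least one contact)")
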
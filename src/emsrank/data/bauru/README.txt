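SAMU-Bauru case study, transcribed from the published demand, service-time and
journey-time tables. Six atoms, 7 basic service units (BSU) and 2 advanced
service units (ASU). Arrival rates are calls per hour per sub atom (serious =
advanced calls "a", regular = basic calls "b"); service times are mean total
response times (travel + on-scene) in minutes; travel times are mean journey
times in minutes between atoms (intra-atom journeys may exceed inter-atom
ones).

Notes:
- The source narrative once refers to atom A1 as "Nacoes" while its demand
  table lists atom 1 as Geisel; this fixture follows the demand table's
  ordering (1 = Geisel, 2 = Nacoes).
- The source does not state the ASU base atoms; both ASUs are pinned at atom 1
  here (a single dedicated group at the central service base).
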
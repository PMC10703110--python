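SAMU-Ribeirao Preto case study, transcribed from the published demand,
service-time and journey-time tables. Five atoms, 9 basic service units (BSU)
and 1 advanced service unit (ASU). Units as in the Bauru fixture.

Notes:
- The source narrative refers to atom A2 as "South" and A4 as "West", while
  its demand table orders the regions Central, North, South, East, West; this
  fixture follows the demand table's ordering (2 = North, 3 = South).
- The source does not state the ASU base atom; the ASU is pinned at atom 1
  (Central) here.
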
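# Original surgical Apgar score (open surgery EBL scale).
name: SAS
ebl_bins:
  - {lo: 0, hi: 100, lo_incl: true, hi_incl: true, points: 3}
  - {lo: 100, hi: 600, lo_incl: false, hi_incl: true, points: 2}
  - {lo: 600, hi: 1000, lo_incl: false, hi_incl: true, points: 1}
  - {lo: 1000, hi: null, lo_incl: false, hi_incl: false, points: 0}
map_bins:
  - {lo: 0, hi: 40, lo_incl: false, hi_incl: false, points: 0}
  - {lo: 40, hi: 55, lo_incl: true, hi_incl: false, points: 1}
  - {lo: 55, hi: 70, lo_incl: true, hi_incl: false, points: 2}
  - {lo: 70, hi: null, lo_incl: true, hi_incl: false, points: 3}
hr_bins:
  - {lo: 0, hi: 55, lo_incl: false, hi_incl: true, points: 4}
  - {lo: 55, hi: 65, lo_incl: false, hi_incl: true, points: 3}
  - {lo: 65, hi: 75, lo_incl: false, hi_incl: true, points: 2}
  - {lo: 75, hi: 85, lo_incl: false, hi_incl: true, points: 1}
  - {lo: 85, hi: null, lo_incl: false, hi_incl: false, points: 0}
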
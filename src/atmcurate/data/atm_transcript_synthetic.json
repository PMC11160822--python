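{
 "name": "ATM-synthetic-exon-table (NM_000051.3-like: 62 coding exons, 9171 nt CDS, 3056 aa)",
 "exons": [
  {
   "index": 2,
   "coding_length_nt": 210,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 3,
   "coding_length_nt": 210,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 4,
   "coding_length_nt": 100,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 5,
   "coding_length_nt": 171,
   "start_phase": 1,
   "end_phase": 1
  },
  {
   "index": 6,
   "coding_length_nt": 167,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 7,
   "coding_length_nt": 174,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 8,
   "coding_length_nt": 148,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 9,
   "coding_length_nt": 161,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 10,
   "coding_length_nt": 192,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 11,
   "coding_length_nt": 96,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 12,
   "coding_length_nt": 210,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 13,
   "coding_length_nt": 80,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 14,
   "coding_length_nt": 170,
   "start_phase": 2,
   "end_phase": 1
  },
  {
   "index": 15,
   "coding_length_nt": 116,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 16,
   "coding_length_nt": 109,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 17,
   "coding_length_nt": 158,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 18,
   "coding_length_nt": 108,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 19,
   "coding_length_nt": 206,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 20,
   "coding_length_nt": 94,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 21,
   "coding_length_nt": 173,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 22,
   "coding_length_nt": 169,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 23,
   "coding_length_nt": 83,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 24,
   "coding_length_nt": 97,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 25,
   "coding_length_nt": 178,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 26,
   "coding_length_nt": 211,
   "start_phase": 1,
   "end_phase": 2
  },
  {
   "index": 27,
   "coding_length_nt": 190,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 28,
   "coding_length_nt": 174,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 29,
   "coding_length_nt": 67,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 30,
   "coding_length_nt": 167,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 31,
   "coding_length_nt": 69,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 32,
   "coding_length_nt": 142,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 33,
   "coding_length_nt": 111,
   "start_phase": 1,
   "end_phase": 1
  },
  {
   "index": 34,
   "coding_length_nt": 87,
   "start_phase": 1,
   "end_phase": 1
  },
  {
   "index": 35,
   "coding_length_nt": 189,
   "start_phase": 1,
   "end_phase": 1
  },
  {
   "index": 36,
   "coding_length_nt": 80,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 37,
   "coding_length_nt": 208,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 38,
   "coding_length_nt": 122,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 39,
   "coding_length_nt": 95,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 40,
   "coding_length_nt": 63,
   "start_phase": 2,
   "end_phase": 2
  },
  {
   "index": 41,
   "coding_length_nt": 191,
   "start_phase": 2,
   "end_phase": 1
  },
  {
   "index": 42,
   "coding_length_nt": 131,
   "start_phase": 1,
   "end_phase": 0
  },
  {
   "index": 43,
   "coding_length_nt": 171,
   "start_phase": 0,
   "end_phase": 0
  },
  {
   "index": 44,
   "coding_length_nt": 115,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 45,
   "coding_length_nt": 133,
   "start_phase": 1,
   "end_phase": 2
  },
  {
   "index": 46,
   "coding_length_nt": 181,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 47,
   "coding_length_nt": 212,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 48,
   "coding_length_nt": 170,
   "start_phase": 2,
   "end_phase": 1
  },
  {
   "index": 49,
   "coding_length_nt": 117,
   "start_phase": 1,
   "end_phase": 1
  },
  {
   "index": 50,
   "coding_length_nt": 184,
   "start_phase": 1,
   "end_phase": 2
  },
  {
   "index": 51,
   "coding_length_nt": 67,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 52,
   "coding_length_nt": 209,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 53,
   "coding_length_nt": 186,
   "start_phase": 2,
   "end_phase": 2
  },
  {
   "index": 54,
   "coding_length_nt": 211,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 55,
   "coding_length_nt": 116,
   "start_phase": 0,
   "end_phase": 2
  },
  {
   "index": 56,
   "coding_length_nt": 117,
   "start_phase": 2,
   "end_phase": 2
  },
  {
   "index": 57,
   "coding_length_nt": 198,
   "start_phase": 2,
   "end_phase": 2
  },
  {
   "index": 58,
   "coding_length_nt": 130,
   "start_phase": 2,
   "end_phase": 0
  },
  {
   "index": 59,
   "coding_length_nt": 130,
   "start_phase": 0,
   "end_phase": 1
  },
  {
   "index": 60,
   "coding_length_nt": 88,
   "start_phase": 1,
   "end_phase": 2
  },
  {
   "index": 61,
   "coding_length_nt": 162,
   "start_phase": 2,
   "end_phase": 2
  },
  {
   "index": 62,
   "coding_length_nt": 152,
   "start_phase": 2,
   "end_phase": 1
  },
  {
   "index": 63,
   "coding_length_nt": 245,
   "start_phase": 1,
   "end_phase": 0
  }
 ],
 "protein_length_aa": 3056,
 "complete": true,
 "schema_version": "1"
}
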
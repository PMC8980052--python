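{
 "note": "synthetic stand-in factor definitions (format demo)",
 "factors": [
  {
   "factor_id": "P1",
   "codes": [
    "A00",
    "A01",
    "A02",
    "A03"
   ],
   "label": "synthetic pre-injury factor 1"
  },
  {
   "factor_id": "P2",
   "codes": [
    "A04",
    "A05",
    "A06",
    "A07"
   ],
   "label": "synthetic pre-injury factor 2"
  },
  {
   "factor_id": "P3",
   "codes": [
    "A08",
    "A09",
    "A10",
    "A11"
   ],
   "label": "synthetic pre-injury factor 3"
  },
  {
   "factor_id": "P4",
   "codes": [
    "A12",
    "A13",
    "A14",
    "A15"
   ],
   "label": "synthetic pre-injury factor 4"
  },
  {
   "factor_id": "P5",
   "codes": [
    "A16",
    "A17",
    "A18",
    "A19"
   ],
   "label": "synthetic pre-injury factor 5"
  },
  {
   "factor_id": "P6",
   "codes": [
    "A20",
    "A21",
    "A22",
    "A23"
   ],
   "label": "synthetic pre-injury factor 6"
  },
  {
   "factor_id": "P7",
   "codes": [
    "A24",
    "A25",
    "A26",
    "A27"
   ],
   "label": "synthetic pre-injury factor 7"
  },
  {
   "factor_id": "P8",
   "codes": [
    "A28",
    "A29",
    "A30",
    "A31"
   ],
   "label": "synthetic pre-injury factor 8"
  },
  {
   "factor_id": "P9",
   "codes": [
    "A32",
    "A33",
    "A34",
    "A35"
   ],
   "label": "synthetic pre-injury factor 9"
  },
  {
   "factor_id": "P10",
   "codes": [
    "A36",
    "A37",
    "A38",
    "A39"
   ],
   "label": "synthetic pre-injury factor 10"
  },
  {
   "factor_id": "P11",
   "codes": [
    "A40",
    "A41",
    "A42",
    "A43"
   ],
   "label": "synthetic pre-injury factor 11"
  },
  {
   "factor_id": "P12",
   "codes": [
    "A44",
    "A45",
    "A46",
    "A47"
   ],
   "label": "synthetic pre-injury factor 12"
  },
  {
   "factor_id": "P13",
   "codes": [
    "A48",
    "A49",
    "A50",
    "A51"
   ],
   "label": "synthetic pre-injury factor 13"
  },
  {
   "factor_id": "P14",
   "codes": [
    "A52",
    "A53",
    "A54",
    "A55"
   ],
   "label": "synthetic pre-injury factor 14"
  },
  {
   "factor_id": "P15",
   "codes": [
    "A56",
    "A57",
    "A58",
    "A59"
   ],
   "label": "synthetic pre-injury factor 15"
  },
  {
   "factor_id": "P16",
   "codes": [
    "A60",
    "A61",
    "A62",
    "A63"
   ],
   "label": "synthetic pre-injury factor 16"
  },
  {
   "factor_id": "P17",
   "codes": [
    "A64",
    "A65",
    "A66",
    "A67"
   ],
   "label": "synthetic pre-injury factor 17"
  },
  {
   "factor_id": "P18",
   "codes": [
    "A68",
    "A69",
    "A70",
    "A71"
   ],
   "label": "synthetic pre-injury factor 18"
  },
  {
   "factor_id": "P19",
   "codes": [
    "A72",
    "A73",
    "A74",
    "A75"
   ],
   "label": "synthetic pre-injury factor 19"
  },
  {
   "factor_id": "P20",
   "codes": [
    "A76",
    "A77",
    "A78",
    "A79"
   ],
   "label": "synthetic pre-injury factor 20"
  },
  {
   "factor_id": "P21",
   "codes": [
    "A80",
    "A81",
    "A82",
    "A83"
   ],
   "label": "synthetic pre-injury factor 21"
  },
  {
   "factor_id": "P22",
   "codes": [
    "A84",
    "A85",
    "A86",
    "A87"
   ],
   "label": "synthetic pre-injury factor 22"
  },
  {
   "factor_id": "P23",
   "codes": [
    "A88",
    "A89",
    "A90",
    "A91"
   ],
   "label": "synthetic pre-injury factor 23"
  },
  {
   "factor_id": "P24",
   "codes": [
    "A92",
    "A93",
    "A94",
    "A95"
   ],
   "label": "synthetic pre-injury factor 24"
  },
  {
   "factor_id": "P25",
   "codes": [
    "A96",
    "A97",
    "A98",
    "A99"
   ],
   "label": "synthetic pre-injury factor 25"
  },
  {
   "factor_id": "P26",
   "codes": [
    "B00",
    "B01",
    "B02",
    "B03"
   ],
   "label": "synthetic pre-injury factor 26"
  },
  {
   "factor_id": "P27",
   "codes": [
    "B04",
    "B05",
    "B06",
    "B07"
   ],
   "label": "synthetic pre-injury factor 27"
  },
  {
   "factor_id": "P28",
   "codes": [
    "B08",
    "B09",
    "B10",
    "B11"
   ],
   "label": "synthetic pre-injury factor 28"
  },
  {
   "factor_id": "P29",
   "codes": [
    "B12",
    "B13",
    "B14",
    "B15"
   ],
   "label": "synthetic pre-injury factor 29"
  },
  {
   "factor_id": "P30",
   "codes": [
    "B16",
    "B17",
    "B18",
    "B19"
   ],
   "label": "synthetic pre-injury factor 30"
  },
  {
   "factor_id": "P31",
   "codes": [
    "B20",
    "B21",
    "B22",
    "B23"
   ],
   "label": "synthetic pre-injury factor 31"
  },
  {
   "factor_id": "P32",
   "codes": [
    "B24",
    "B25",
    "B26",
    "B27"
   ],
   "label": "synthetic pre-injury factor 32"
  },
  {
   "factor_id": "P33",
   "codes": [
    "B28",
    "B29",
    "B30",
    "B31"
   ],
   "label": "synthetic pre-injury factor 33"
  },
  {
   "factor_id": "P34",
   "codes": [
    "B32",
    "B33",
    "B34",
    "B35"
   ],
   "label": "synthetic pre-injury factor 34"
  },
  {
   "factor_id": "P35",
   "codes": [
    "B36",
    "B37",
    "B38",
    "B39"
   ],
   "label": "synthetic pre-injury factor 35"
  },
  {
   "factor_id": "P36",
   "codes": [
    "B40",
    "B41",
    "B42",
    "B43"
   ],
   "label": "synthetic pre-injury factor 36"
  },
  {
   "factor_id": "P37",
   "codes": [
    "B44",
    "B45",
    "B46",
    "B47"
   ],
   "label": "synthetic pre-injury factor 37"
  },
  {
   "factor_id": "P38",
   "codes": [
    "B48",
    "B49",
    "B50",
    "B51"
   ],
   "label": "synthetic pre-injury factor 38"
  },
  {
   "factor_id": "P39",
   "codes": [
    "B52",
    "B53",
    "B54",
    "B55"
   ],
   "label": "synthetic pre-injury factor 39"
  },
  {
   "factor_id": "P40",
   "codes": [
    "B56",
    "B57",
    "B58",
    "B59"
   ],
   "label": "synthetic pre-injury factor 40"
  },
  {
   "factor_id": "P41",
   "codes": [
    "B60",
    "B61",
    "B62",
    "B63"
   ],
   "label": "synthetic pre-injury factor 41"
  },
  {
   "factor_id": "P42",
   "codes": [
    "B64",
    "B65",
    "B66",
    "B67"
   ],
   "label": "synthetic pre-injury factor 42"
  },
  {
   "factor_id": "P43",
   "codes": [
    "B68",
    "B69",
    "B70",
    "B71"
   ],
   "label": "synthetic pre-injury factor 43"
  }
 ]
}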
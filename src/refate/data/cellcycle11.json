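{
 "nodes": [
  {
   "id": "Cln3",
   "label": "Cln3",
   "kind": "protein",
   "self_mode": "degradation"
  },
  {
   "id": "MBF",
   "label": "MBF",
   "kind": "protein",
   "self_mode": "sustaining"
  },
  {
   "id": "SBF",
   "label": "SBF",
   "kind": "protein",
   "self_mode": "sustaining"
  },
  {
   "id": "Cln12",
   "label": "Cln12",
   "kind": "protein",
   "self_mode": "degradation"
  },
  {
   "id": "Cdh1",
   "label": "Cdh1",
   "kind": "protein",
   "self_mode": "sustaining"
  },
  {
   "id": "Swi5",
   "label": "Swi5",
   "kind": "protein",
   "self_mode": "degradation"
  },
  {
   "id": "Cdc20",
   "label": "Cdc20",
   "kind": "protein",
   "self_mode": "degradation"
  },
  {
   "id": "Clb56",
   "label": "Clb56",
   "kind": "protein",
   "self_mode": "sustaining"
  },
  {
   "id": "Sic1",
   "label": "Sic1",
   "kind": "protein",
   "self_mode": "sustaining"
  },
  {
   "id": "Clb12",
   "label": "Clb12",
   "kind": "protein",
   "self_mode": "sustaining"
  },
  {
   "id": "Mcm1",
   "label": "Mcm1",
   "kind": "protein",
   "self_mode": "degradation"
  }
 ],
 "edges": [
  {
   "source": "Cln3",
   "target": "MBF",
   "sign": 1
  },
  {
   "source": "Cln3",
   "target": "SBF",
   "sign": 1
  },
  {
   "source": "MBF",
   "target": "Clb56",
   "sign": 1
  },
  {
   "source": "SBF",
   "target": "Cln12",
   "sign": 1
  },
  {
   "source": "Cln12",
   "target": "Sic1",
   "sign": -1
  },
  {
   "source": "Cln12",
   "target": "Cdh1",
   "sign": -1
  },
  {
   "source": "Clb56",
   "target": "Mcm1",
   "sign": 1
  },
  {
   "source": "Clb56",
   "target": "Clb12",
   "sign": 1
  },
  {
   "source": "Clb56",
   "target": "Sic1",
   "sign": -1
  },
  {
   "source": "Clb56",
   "target": "Cdh1",
   "sign": -1
  },
  {
   "source": "Clb12",
   "target": "Mcm1",
   "sign": 1
  },
  {
   "source": "Clb12",
   "target": "Cdc20",
   "sign": 1
  },
  {
   "source": "Clb12",
   "target": "Sic1",
   "sign": -1
  },
  {
   "source": "Clb12",
   "target": "Cdh1",
   "sign": -1
  },
  {
   "source": "Clb12",
   "target": "MBF",
   "sign": -1
  },
  {
   "source": "Clb12",
   "target": "SBF",
   "sign": -1
  },
  {
   "source": "Clb12",
   "target": "Swi5",
   "sign": -1
  },
  {
   "source": "Mcm1",
   "target": "Clb12",
   "sign": 1
  },
  {
   "source": "Mcm1",
   "target": "Cdc20",
   "sign": 1
  },
  {
   "source": "Mcm1",
   "target": "Swi5",
   "sign": 1
  },
  {
   "source": "Cdc20",
   "target": "Swi5",
   "sign": 1
  },
  {
   "source": "Cdc20",
   "target": "Cdh1",
   "sign": 1
  },
  {
   "source": "Cdc20",
   "target": "Sic1",
   "sign": 1
  },
  {
   "source": "Cdc20",
   "target": "Clb56",
   "sign": -1
  },
  {
   "source": "Cdc20",
   "target": "Clb12",
   "sign": -1
  },
  {
   "source": "Swi5",
   "target": "Sic1",
   "sign": 1
  },
  {
   "source": "Sic1",
   "target": "Clb56",
   "sign": -1
  },
  {
   "source": "Sic1",
   "target": "Clb12",
   "sign": -1
  },
  {
   "source": "Cdh1",
   "target": "Clb12",
   "sign": -1
  }
 ],
 "signals": {}
}
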
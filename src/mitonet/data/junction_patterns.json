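{
 "3": [
  {
   "label": "terminate_all",
   "links": [],
   "terminated": [
    0,
    1,
    2
   ]
  },
  {
   "label": "pass_01_terminate_2",
   "links": [
    [
     0,
     1
    ]
   ],
   "terminated": [
    2
   ]
  },
  {
   "label": "pass_02_terminate_1",
   "links": [
    [
     0,
     2
    ]
   ],
   "terminated": [
    1
   ]
  },
  {
   "label": "pass_12_terminate_0",
   "links": [
    [
     1,
     2
    ]
   ],
   "terminated": [
    0
   ]
  },
  {
   "label": "pass_01_abut_2",
   "links": [
    [
     0,
     1
    ]
   ],
   "terminated": [
    2
   ]
  },
  {
   "label": "pass_02_abut_1",
   "links": [
    [
     0,
     2
    ]
   ],
   "terminated": [
    1
   ]
  },
  {
   "label": "pass_12_abut_0",
   "links": [
    [
     1,
     2
    ]
   ],
   "terminated": [
    0
   ]
  },
  {
   "label": "fuse_all",
   "links": [
    [
     0,
     1
    ],
    [
     0,
     2
    ],
    [
     1,
     2
    ]
   ],
   "terminated": []
  }
 ]
}
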
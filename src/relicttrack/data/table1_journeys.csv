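individual,season,year,departure,arrival,n_stopovers,segments_km
G3,autumn,2008,2008-08-01,2008-08-03,0,810
G3,autumn,2009,2009-07-31,2009-08-03,1,470/420
G4,autumn,2008,2008-07-26,2008-09-01,3,400/40/30/420
G4,autumn,2009,2009-07-28,2009-08-27,5,290/50/70/50/30/500
G4,autumn,2010,2010-08-11,2010-09-11,2,440/30/420
G4,autumn,2011,2011-07-26,2011-09-06,2,350/90/460
G5,autumn,2008,2008-08-03,2008-08-19,1,440/470
G5,autumn,2009,2009-07-18,2009-08-11,3,510/80/40/410
G5,autumn,2010,2010-07-30,2010-08-14,2,380/90/430
G5,autumn,2011,2011-07-27,2011-07-28,0,670
G5,autumn,2012,2012-08-03,2012-08-17,1,490/440
G6,autumn,2008,2008-08-02,2008-08-12,1,490/470
G7,autumn,2008,2008-07-22,2008-08-03,2,420/100/370
G7,autumn,2009,2009-07-21,2009-07-22,0,670
G8,autumn,2010,2010-09-02,2010-09-24,2,240/120/380
G9,autumn,2010,2010-07-30,2010-08-14,1,390/300
G10,autumn,2010,2010-08-13,2010-08-14,0,670
G11,autumn,2010,2010-07-26,2010-08-05,2,490/100/300
G11,autumn,2011,2011-07-21,2011-07-23,0,710
G11,autumn,2012,2012-07-21,2012-07-23,0,740
G3,spring,2009,2009-04-08,2009-04-15,1,470/380
G4,spring,2009,2009-04-04,2009-04-06,0,700
G4,spring,2010,2010-04-05,2010-04-09,0,690
G4,spring,2011,2011-04-05,2011-04-12,0,680
G4,spring,2012,2012-04-06,2012-04-07,0,680
G5,spring,2009,2009-03-31,2009-04-06,0,670
G5,spring,2010,2010-04-01,2010-04-03,0,710
G5,spring,2011,2011-04-08,2011-04-11,0,680
G5,spring,2012,2012-04-10,2012-04-14,0,670
G7,spring,2009,2009-04-10,2009-04-13,1,810/240
G7,spring,2010,2010-04-02,2010-04-07,0,670
G11,spring,2011,2011-04-03,2011-04-05,1,550/180
G11,spring,2012,2012-03-31,2012-04-03,0,810
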
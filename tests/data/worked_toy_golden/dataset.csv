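patient_id,practice_id,group_id,exposed_flag,match_order,sex,age_at_index,townsend_quintile,ethnicity,index_date,patient_start,patient_end,exit_date,follow_up_days,IschemicHeartDisease_event,IschemicHeartDisease_date,IschemicHeartDisease_days,Stroke_event,Stroke_date,Stroke_days,HeartFailure_event,HeartFailure_date,HeartFailure_days,BMI_value,BMI_date,Smoking_value,Smoking_date
pt002,pracA,1,1,,male,57,4,white,2006-09-10,1999-07-15,2018-05-01,2018-05-01,4251,0,,,0,,,0,,,,,,
pt008,pracA,1,0,1.0,male,57,4,white,2006-09-10,1999-04-18,2018-05-01,2014-09-01,2913,0,,,1,2014-09-01,2913.0,0,,,,,,
pt031,pracB,1,0,2.0,male,52,3,white,2006-09-10,2005-04-09,2019-11-30,2019-11-30,4829,0,,,0,,,0,,,,,,
pt022,pracB,2,1,,male,51,2,white,2009-01-30,2003-02-02,2019-11-30,2016-02-18,2575,0,,,0,,,1,2016-02-18,2575.0,33.1,2008-12-25,,
pt023,pracB,2,0,1.0,male,50,2,white,2009-01-30,2003-05-05,2019-11-30,2019-11-30,3956,0,,,0,,,0,,,27.7,2008-10-01,,
pt024,pracB,2,0,2.0,male,52,4,white,2009-01-30,2004-03-02,2019-11-30,2019-11-30,3956,0,,,0,,,0,,,,,,2005-05-05
pt021,pracB,3,1,,female,73,4,white,2008-03-20,2003-01-01,2019-11-30,2013-11-23,2074,0,,,1,2013-11-23,2074.0,0,,,,,,
pt032,pracB,3,0,1.0,female,71,2,white,2008-03-20,2003-07-07,2019-11-30,2019-11-30,4272,0,,,0,,,0,,,,,,
pt034,pracB,3,0,2.0,female,69,4,white,2008-03-20,2004-02-28,2019-11-30,2019-11-30,4272,0,,,0,,,0,,,,,,
pt001,pracA,4,1,,female,52,2,white,2007-06-15,2000-02-01,2018-05-01,2010-02-10,971,1,2010-02-10,971.0,0,,,0,,,30.2,2007-05-30,,2003-03-03
pt010,pracA,4,0,1.0,female,52,2,,2007-06-15,2000-09-08,2012-03-04,2012-03-04,1724,0,,,0,,,0,,,29.7,2007-01-05,,
pt019,pracA,4,0,2.0,female,57,1,white,2007-06-15,2000-03-02,2018-05-01,2018-05-01,3973,0,,,0,,,0,,,,,,
pt012,pracA,5,1,,female,56,2,white,2009-10-01,2001-11-11,2018-05-01,2015-07-07,2105,0,,,0,,,1,2015-07-07,2105.0,,,,
pt039,pracA,5,0,1.0,female,56,2,white,2009-10-01,2000-06-05,2018-05-01,2018-05-01,3134,0,,,0,,,0,,,,,,2004-08-08
pt006,pracA,5,0,2.0,female,54,2,white,2009-10-01,2000-01-05,2018-05-01,2018-05-01,3134,0,,,0,,,0,,,,,,2001-01-01
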